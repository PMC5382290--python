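"""Binary morphology with Euclidean balls via distance transforms.

Erosion by a ball of radius ``r`` keeps the voxels whose distance to
the background exceeds ``r``; dilation brings in voxels within ``r``
of the foreground.  Both match the structuring-element definitions
(``ball(r) = {x : |x| <= r}``) exactly but avoid materializing large
elements, which matters for the opening radii used on whole clusters
(~20 voxels).  Inputs are padded so the image border behaves as
background.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def _pad(mask: np.ndarray, r_vox: float) -> tuple[np.ndarray, tuple[slice, ...]]:
    pad = int(np.ceil(r_vox)) + 1
    crop = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    return np.pad(mask, pad), crop


def ball_erosion(mask: np.ndarray, r_vox: float) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    padded, crop = _pad(mask, r_vox)
    return (ndimage.distance_transform_edt(padded) > r_vox)[crop]


def ball_dilation(mask: np.ndarray, r_vox: float) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    padded, crop = _pad(mask, r_vox)
    return (ndimage.distance_transform_edt(~padded) <= r_vox)[crop]


def ball_opening(mask: np.ndarray, r_vox: float) -> np.ndarray:
    """Erosion followed by dilation: removes structures thinner than
    the ball; anti-extensive (``opening(B)`` is a subset of ``B``)."""
    mask = np.asarray(mask, dtype=bool)
    padded, crop = _pad(mask, r_vox)
    eroded = ndimage.distance_transform_edt(padded) > r_vox
    return (ndimage.distance_transform_edt(~eroded) <= r_vox)[crop]


def ball_closing(mask: np.ndarray, r_vox: float) -> np.ndarray:
    """Dilation followed by erosion: fills gaps narrower than the ball."""
    mask = np.asarray(mask, dtype=bool)
    padded, crop = _pad(mask, r_vox)
    dilated = ndimage.distance_transform_edt(~padded) <= r_vox
    return (ndimage.distance_transform_edt(dilated) > r_vox)[crop]
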