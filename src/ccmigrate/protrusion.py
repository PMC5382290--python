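"""Cluster external protrusions and 3D surface morphodynamics.

A cluster external protrusion is an elongated extension along the
cluster's outward normal, thinner than the cluster body.  Fitting the
mean border-cell volume to a sphere gives a radius ``r``; opening the
binary cluster mask ``B`` with a ball of that radius removes every
structure thinner than the ball, so the residue ``B \\ opening(B)`` is
the protrusion.  What remains after opening is the spheroid cluster
body, whose mass-center displacement defines the cluster speed and
direction.

Surface morphodynamics assumes the sampling interval is short enough
that the deformation between consecutive frames is linear: each
surface voxel of the new frame lying in previously unoccupied space is
a positive (extension) sample whose magnitude is the minimum distance
to the old surface, and symmetrically for negative (retraction)
samples.  Per-cell summaries are the maximum positive/negative
deformation (MPD/MND) and the positive/negative deformation energies
(PDE/NDE, the summed magnitudes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import ValidationError
from .morphology import ball_dilation, ball_erosion, ball_opening
from .tracking import TrackTable

logger = logging.getLogger(__name__)


class ConfigurationError(ValidationError):
    pass


def sphere_radius_from_volume(volume_um3: float) -> float:
    """Radius of the sphere with the given volume: ``(3V / 4 pi)^(1/3)``."""
    return float((3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def detect_protrusion(cluster: np.ndarray, r_um: float,
                      voxel_um: float) -> np.ndarray:
    """``B \\ opening(B, ball(r))``: the anti-extensive opening residue.

    On a voxel grid the opening of even a smooth body leaves a
    sub-voxel-thick residue film along its surface; residue without a
    1-voxel-erodible core is therefore discarded (a real protrusion is
    several voxels thick), keeping only residue within reach of such a
    core.
    """
    if r_um < voxel_um:
        raise ConfigurationError(
            f"opening radius {r_um} um is below one voxel ({voxel_um} um)")
    mask = np.asarray(cluster, dtype=bool)
    if not mask.any():
        return mask.copy()
    fg = np.argwhere(mask)
    lo = np.maximum(fg.min(axis=0) - 1, 0)
    hi = np.minimum(fg.max(axis=0) + 2, mask.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    residue = mask[box] & ~ball_opening(mask[box], r_um / voxel_um)
    core = ball_erosion(residue, 1.0)
    residue &= ball_dilation(core, 2.0)
    out = np.zeros_like(mask)
    out[box] = residue
    return out


@dataclass
class ProtrusionRecord:
    frame: int
    volume_um3: float
    rate_um3_min: float
    direction: np.ndarray | None     # unit (z, y, x) or None when undefined
    owner: int | None
    body_center_um: np.ndarray
    voxels: np.ndarray | None = None

    def to_row(self) -> dict:
        d = self.direction if self.direction is not None else (np.nan,) * 3
        return {"frame": self.frame, "volume_um3": self.volume_um3,
                "rate_um3_min": self.rate_um3_min,
                "dz": d[0], "dy": d[1], "dx": d[2],
                "owner": self.owner if self.owner is not None else 0,
                "body_z_um": self.body_center_um[0],
                "body_y_um": self.body_center_um[1],
                "body_x_um": self.body_center_um[2]}


def protrusion_stats(protrusion: np.ndarray, cells: np.ndarray,
                     cluster: np.ndarray, voxel_um: float,
                     frame_interval: float, frame: int = 0,
                     r_um: float | None = None) -> ProtrusionRecord:
    """Volume, growth rate, direction and owner of a protrusion mask.

    Direction is the normalized vector from the cluster-body mass
    center to the protrusion mass center (None when the protrusion is
    empty or symmetric); the owner is the modal cell label inside the
    protrusion.  The body center is the mass center of the opened
    cluster (protrusions removed).
    """
    prot = np.asarray(protrusion, dtype=bool)
    cluster = np.asarray(cluster, dtype=bool)
    body = cluster & ~prot
    if not body.any():
        body = cluster
    body_center = np.argwhere(body).mean(axis=0) * voxel_um
    volume = float(prot.sum()) * voxel_um**3
    if volume == 0:
        return ProtrusionRecord(frame=frame, volume_um3=0.0, rate_um3_min=0.0,
                                direction=None, owner=None,
                                body_center_um=body_center)
    prot_center = np.argwhere(prot).mean(axis=0) * voxel_um
    vec = prot_center - body_center
    norm = np.linalg.norm(vec)
    if norm < 0.25 * voxel_um:
        logger.warning("frame %d: protrusion direction undefined (symmetric)", frame)
        direction = None
    else:
        direction = vec / norm
    labels_inside = np.asarray(cells)[prot]
    labels_inside = labels_inside[labels_inside > 0]
    owner = int(np.bincount(labels_inside).argmax()) if labels_inside.size else None
    return ProtrusionRecord(frame=frame, volume_um3=volume,
                            rate_um3_min=volume / frame_interval,
                            direction=direction, owner=owner,
                            body_center_um=body_center, voxels=prot)


def analyse_protrusions(cluster_masks: np.ndarray, cells: np.ndarray,
                        mean_border_volume_um3: float, voxel_um: float,
                        frame_interval: float) -> tuple[list[ProtrusionRecord], np.ndarray]:
    """Per-frame protrusion records plus cluster body speed vectors.

    Returns the records and the ``(T-1, 3)`` body velocity vectors
    ``v(t) = (m(t+1) - m(t)) / dt`` in um/min.
    """
    r = sphere_radius_from_volume(mean_border_volume_um3)
    T = cluster_masks.shape[0]
    records = []
    for t in range(T):
        prot = detect_protrusion(cluster_masks[t], r, voxel_um)
        records.append(protrusion_stats(prot, cells[t], cluster_masks[t],
                                        voxel_um, frame_interval, frame=t,
                                        r_um=r))
    centers = np.stack([rec.body_center_um for rec in records])
    velocity = np.diff(centers, axis=0) / frame_interval
    return records, velocity


def protrusion_alignment(prot_dirs: np.ndarray, cluster_dirs: np.ndarray
                         ) -> tuple[np.ndarray, float]:
    """PA(t): signed dot product of unit protrusion and cluster
    directions, in [-1, 1]; +1 aligned with migration, -1 opposite.

    Frames where either vector is undefined (NaN) are excluded from
    the mean; an empty series yields NaN with a warning.
    """
    p = np.asarray(prot_dirs, dtype=float).reshape(-1, 3)
    c = np.asarray(cluster_dirs, dtype=float).reshape(-1, 3)
    if p.shape != c.shape:
        raise ValidationError("protrusion and cluster series must pair frame-wise")
    with np.errstate(invalid="ignore"):
        p = p / np.linalg.norm(p, axis=1, keepdims=True)
        c = c / np.linalg.norm(c, axis=1, keepdims=True)
    pa = np.einsum("ij,ij->i", p, c)
    valid = ~np.isnan(pa)
    if not valid.any():
        logger.warning("no frame with both protrusion and cluster direction")
        return pa, float("nan")
    return pa, float(pa[valid].mean())


def protrusion_coupling(records: list["ProtrusionRecord"],
                        body_velocity: np.ndarray,
                        voxel_um: float = 1.0) -> tuple[float, float]:
    """CD and CS: how protrusion geometry couples to cluster motion.

    CD correlates the magnitude of the per-frame combined protrusion
    direction — the sum of unit direction vectors of the individual
    protrusions (connected components of the residue) — with the
    cluster speed; CS correlates the protrusion volume with the
    cluster speed.  Frames without protrusions contribute zeros.
    """
    T = len(records) - 1
    combined = np.zeros(T)
    volumes = np.zeros(T)
    for t in range(T):
        rec = records[t]
        volumes[t] = rec.volume_um3
        if rec.voxels is None or not rec.voxels.any():
            continue
        labelled, n = ndimage.label(rec.voxels)
        total = np.zeros(3)
        for comp in range(1, n + 1):
            center_um = np.argwhere(labelled == comp).mean(axis=0) * voxel_um
            vec = center_um - rec.body_center_um
            norm = np.linalg.norm(vec)
            if norm > 0:
                total += vec / norm
        combined[t] = np.linalg.norm(total)
    speeds = np.linalg.norm(body_velocity, axis=1)
    return pearson(combined, speeds), pearson(volumes, speeds)


def pearson(x, y) -> float:
    """Pearson correlation ``E[(X-mu_x)(Y-mu_y)] / (sigma_x sigma_y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = ~(np.isnan(x) | np.isnan(y))
    x, y = x[valid], y[valid]
    if x.size < 3:
        raise ValidationError("correlation needs at least 3 paired samples")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero variance: correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class DeformationEntry:
    """Signed surface-displacement samples for one cell, one frame pair."""

    cell: int
    frame: int
    positive_points: np.ndarray    # (n_pos, 3) voxel coords on the new surface
    positive_magnitudes: np.ndarray  # um
    positive_vectors: np.ndarray   # (n_pos, 3) um, old-surface -> new point
    negative_points: np.ndarray
    negative_magnitudes: np.ndarray

    @property
    def mpd(self) -> float:
        return float(self.positive_magnitudes.max()) if self.positive_magnitudes.size else 0.0

    @property
    def mnd(self) -> float:
        return float(self.negative_magnitudes.max()) if self.negative_magnitudes.size else 0.0

    @property
    def pde(self) -> float:
        return float(self.positive_magnitudes.sum())

    @property
    def nde(self) -> float:
        return float(self.negative_magnitudes.sum())

    def positive_sum_vector(self) -> np.ndarray:
        """Summed positive deformation vector (um) — the cell's
        internal-extension direction for rotation association."""
        if self.positive_vectors.size == 0:
            return np.zeros(3)
        return self.positive_vectors.sum(axis=0)


def _surface(mask: np.ndarray) -> np.ndarray:
    """6-connected boundary voxels of a binary set."""
    cross = ndimage.generate_binary_structure(3, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=cross, border_value=0)


def deformation_map(cell_t: np.ndarray, cell_t1: np.ndarray, voxel_um: float,
                    cell: int = 0, frame: int = 0) -> DeformationEntry:
    """Linear minimum-distance mapping between two cell surfaces.

    Positive samples: surface voxels of the new frame outside the old
    cell — the surface moved into space not previously occupied — with
    magnitude the distance to the nearest old-surface voxel.  Negative
    samples mirror this for retraction.  A voxel can never be both.
    """
    a = np.asarray(cell_t, dtype=bool)
    b = np.asarray(cell_t1, dtype=bool)
    if not a.any() or not b.any():
        raise ValidationError("deformation mapping requires two nonempty cells")
    # crop to the joint bounding box (plus a margin) — the distance
    # transforms only matter near the two surfaces
    both = np.argwhere(a | b)
    lo = np.maximum(both.min(axis=0) - 2, 0)
    hi = np.minimum(both.max(axis=0) + 3, a.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    a = a[box]
    b = b[box]
    surf_a = _surface(a)
    surf_b = _surface(b)
    dist_a, idx_a = ndimage.distance_transform_edt(~surf_a, return_indices=True)
    dist_b = ndimage.distance_transform_edt(~surf_b)
    pos_pts = np.argwhere(surf_b & ~a)
    neg_pts = np.argwhere(surf_a & ~b)
    pos_mag = dist_a[tuple(pos_pts.T)] * voxel_um
    neg_mag = dist_b[tuple(neg_pts.T)] * voxel_um
    nearest = np.stack([idx_a[d][tuple(pos_pts.T)] for d in range(3)], axis=1)
    pos_vec = (pos_pts - nearest) * voxel_um
    return DeformationEntry(cell=cell, frame=frame,
                            positive_points=pos_pts + lo,
                            positive_magnitudes=pos_mag,
                            positive_vectors=pos_vec,
                            negative_points=neg_pts + lo,
                            negative_magnitudes=neg_mag)


def deformation_fields(cells: np.ndarray, voxel_um: float
                       ) -> list[list[DeformationEntry]]:
    """Deformation entries for every cell over every frame pair of a
    ``(T, Z, Y, X)`` cell label movie."""
    T = cells.shape[0]
    labels = [int(l) for l in np.unique(cells) if l != 0]
    out = []
    for t in range(T - 1):
        entries = []
        for lab in labels:
            entries.append(deformation_map(cells[t] == lab, cells[t + 1] == lab,
                                           voxel_um, cell=lab, frame=t))
        out.append(entries)
    return out


def mobility_params(tracks_nuclei: TrackTable, tracks_cells: TrackTable,
                    fields: list[list[DeformationEntry]]) -> pd.DataFrame:
    """Per-frame mobility table: NS, CS, MPD, MND, PDE, NDE.

    Nucleus/cell speeds are identity-averaged over the cluster; the
    four deformation summaries are averaged over cells.
    """
    T = len(fields)
    if tracks_nuclei.n_frames - 1 != T or tracks_cells.n_frames - 1 != T:
        raise ValidationError("tracks and deformation fields cover different frames")
    rows = []
    for t in range(T):
        entries = fields[t]
        rows.append({
            "frame": t,
            "NS": float(np.nanmean(tracks_nuclei.speeds[t])),
            "CS": float(np.nanmean(tracks_cells.speeds[t])),
            "MPD": float(np.mean([e.mpd for e in entries])),
            "MND": float(np.mean([e.mnd for e in entries])),
            "PDE": float(np.mean([e.pde for e in entries])),
            "NDE": float(np.mean([e.nde for e in entries])),
        })
    return pd.DataFrame(rows)


@dataclass
class RotationAssociation:
    """Cluster-rotation vs protrusion-rotation coupling per frame."""

    R: np.ndarray          # (T-1, 3) combined cluster rotating vector
    Q: np.ndarray          # (T-1, 3) combined protrusion rotating vector
    angles_deg: np.ndarray  # NaN where either vector vanishes
    correlation: float      # Pearson of |R| and |Q|

    @property
    def mean_angle_deg(self) -> float:
        valid = ~np.isnan(self.angles_deg)
        return float(self.angles_deg[valid].mean()) if valid.any() else float("nan")


def rotation_association(tracks: TrackTable,
                         fields: list[list[DeformationEntry]],
                         cluster_centers: np.ndarray) -> RotationAssociation:
    """Angle between the combined cluster rotating vector
    ``R = sum_k r_k x v_k`` (nucleus displacements) and the combined
    protrusion rotating vector ``Q = sum_k r_k x u_k`` (summed positive
    deformation vectors), plus the movie-wide Pearson correlation of
    their magnitudes."""
    T = len(fields)
    if tracks.n_frames - 1 != T:
        raise ValidationError("tracks and deformation fields cover different frames")
    if T < 3:
        raise ValidationError("rotation association needs at least 3 frame pairs")
    label_index = {lab: k for k, lab in enumerate(tracks.labels)}
    R = np.zeros((T, 3))
    Q = np.zeros((T, 3))
    activity = np.zeros(T)  # total positive deformation energy per frame
    for t in range(T):
        activity[t] = sum(entry.pde for entry in fields[t])
        cm = np.asarray(cluster_centers[t], dtype=float)
        r = tracks.centers[t] - cm
        norms = np.linalg.norm(r, axis=1)
        r_hat = np.where(norms[:, None] > 0, r / np.clip(norms, 1e-12, None)[:, None], 0.0)
        R[t] = np.cross(r_hat, tracks.displacements[t]).sum(axis=0)
        for entry in fields[t]:
            k = label_index.get(entry.cell)
            if k is None:
                continue
            Q[t] += np.cross(r_hat[k], entry.positive_sum_vector())
    nR = np.linalg.norm(R, axis=1)
    nQ = np.linalg.norm(Q, axis=1)
    angles = np.full(T, np.nan)
    # a frame is flagged (NaN angle) when either vector vanishes; Q must
    # carry a coherent fraction of the frame's deformation activity —
    # incoherent (e.g. purely radial) extensions cancel in the cross-
    # product sum and must not produce spurious angles
    ok = (nR > 1e-12) & (nQ > 0.25 * activity)
    cosang = np.einsum("ij,ij->i", R[ok], Q[ok]) / (nR[ok] * nQ[ok])
    angles[ok] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    corr = pearson(nR, nQ)
    return RotationAssociation(R=R, Q=Q, angles_deg=angles, correlation=corr)
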