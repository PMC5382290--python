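"""Frame-to-frame association of nuclei/cells by global assignment.

Each pair of consecutive frames yields a square confidence matrix

    S_ij = (|Omega_i(t) n Omega_j(t+1)| + 1) / (||c_i(t) - c_j(t+1)|| + eps)

favouring pairs that overlap more and lie closer; the ``+1`` keeps
fully disjoint pairs rankable by distance, which is what lets fast
movers be recovered.  The bijection maximizing the summed confidence is
found by the Hungarian algorithm (as min-cost assignment on negated
scores) and chained into stable track labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import LabelVolume, ValidationError


@dataclass
class ConfidenceMatrix:
    """Tracking confidence between segments at t (rows) and t+1 (cols)."""

    scores: np.ndarray
    labels_t: np.ndarray
    labels_t1: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValidationError(f"confidence matrix must be square, got {self.scores.shape}")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("confidence matrix contains non-finite entries")


@dataclass
class TrackTable:
    """Per-entity, per-frame centers and derived kinematics.

    ``centers`` has shape ``(T, K, 3)`` in micrometres, ordered like
    ``labels``.  Displacements ``v_k(t) = c_k(t+1) - c_k(t)`` give speeds
    ``|v|/dt`` (um/min) and unit directions ``d_k(t)``; the direction is
    NaN wherever the displacement is zero.
    """

    centers: np.ndarray
    labels: list[int]
    identity_map: dict[int, str]
    frame_interval: float
    displacements: np.ndarray = field(init=False)
    speeds: np.ndarray = field(init=False)
    directions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 3 or self.centers.shape[2] != 3:
            raise ValidationError(f"centers must have shape (T, K, 3), got {self.centers.shape}")
        if self.centers.shape[1] != len(self.labels):
            raise ValidationError("one label required per tracked entity")
        self.displacements = np.diff(self.centers, axis=0)
        norms = np.linalg.norm(self.displacements, axis=2)
        self.speeds = norms / self.frame_interval
        with np.errstate(invalid="ignore", divide="ignore"):
            self.directions = self.displacements / norms[..., None]
        self.directions[norms == 0] = np.nan

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_entities(self) -> int:
        return self.centers.shape[1]

    def select(self, identity: str) -> "TrackTable":
        """Sub-table restricted to one identity (``polar`` or ``border``)."""
        keep = [i for i, lab in enumerate(self.labels) if self.identity_map[lab] == identity]
        return TrackTable(
            centers=self.centers[:, keep],
            labels=[self.labels[i] for i in keep],
            identity_map=self.identity_map,
            frame_interval=self.frame_interval,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        T, K, _ = self.centers.shape
        for k, lab in enumerate(self.labels):
            for t in range(T):
                z, y, x = self.centers[t, k]
                if t < T - 1:
                    speed = self.speeds[t, k]
                    dz, dy, dx = self.directions[t, k]
                else:
                    speed, dz, dy, dx = np.nan, np.nan, np.nan, np.nan
                rows.append({
                    "label": lab, "identity": self.identity_map.get(lab, ""),
                    "frame": t, "z_um": z, "y_um": y, "x_um": x,
                    "speed_um_min": speed, "dz": dz, "dy": dy, "dx": dx,
                })
        return pd.DataFrame(rows)


def segment_centers(frame: np.ndarray, voxel_size_zyx) -> tuple[np.ndarray, np.ndarray]:
    """Labels present in a label frame and their centroids in micrometres."""
    labels = np.unique(frame)
    labels = labels[labels != 0]
    voxel = np.asarray(voxel_size_zyx, dtype=float)
    centers = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        idx = np.argwhere(frame == lab)
        centers[i] = idx.mean(axis=0) * voxel
    return labels, centers


def tracking_confidence(frame_t: np.ndarray, frame_t1: np.ndarray,
                        voxel_size_zyx, epsilon: float) -> ConfidenceMatrix:
    """Confidence matrix between the segments of two consecutive frames.

    Overlap is counted in voxels; center distance is Euclidean in
    micrometres.
    """
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    labels_t, centers_t = segment_centers(frame_t, voxel_size_zyx)
    labels_t1, centers_t1 = segment_centers(frame_t1, voxel_size_zyx)
    if len(labels_t) != len(labels_t1):
        raise ValidationError(
            f"segment count mismatch: {len(labels_t)} at t vs {len(labels_t1)} at t+1"
        )
    # joint histogram of co-occurring labels gives all pairwise overlaps
    both = (frame_t > 0) & (frame_t1 > 0)
    pair_index = {lab: i for i, lab in enumerate(labels_t)}
    pair_index1 = {lab: j for j, lab in enumerate(labels_t1)}
    overlap = np.zeros((len(labels_t), len(labels_t1)))
    if both.any():
        a = frame_t[both].ravel()
        b = frame_t1[both].ravel()
        pairs, counts = np.unique(np.stack([a, b]), axis=1, return_counts=True)
        for (la, lb), n in zip(pairs.T, counts):
            overlap[pair_index[la], pair_index1[lb]] = n
    dist = np.linalg.norm(centers_t[:, None, :] - centers_t1[None, :, :], axis=2)
    scores = (overlap + 1.0) / (dist + epsilon)
    return ConfidenceMatrix(scores=scores, labels_t=labels_t, labels_t1=labels_t1,
                            epsilon=epsilon)


def _optimal_total(scores: np.ndarray) -> float:
    rows, cols = linear_sum_assignment(-scores)
    return float(scores[rows, cols].sum())


def assign_tracks(confidence: ConfidenceMatrix | np.ndarray) -> np.ndarray:
    """Permutation ``sigma`` maximizing ``sum_i S[i, sigma[i]]``.

    Among tied optima the lexicographically smallest permutation is
    returned, fixed row by row.
    """
    scores = confidence.scores if isinstance(confidence, ConfidenceMatrix) else np.asarray(
        confidence, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise ValidationError(f"assignment requires a square matrix, got {scores.shape}")
    c = scores.shape[0]
    best = _optimal_total(scores)
    tol = 1e-9 * max(1.0, abs(best))
    sigma = np.empty(c, dtype=int)
    free_cols = list(range(c))
    sub = scores.copy()
    for i in range(c):
        for pos, j in enumerate(list(free_cols)):
            rest = np.delete(np.delete(sub, 0, axis=0), pos, axis=1)
            total = sub[0, pos] + (_optimal_total(rest) if rest.size else 0.0)
            if total >= best - tol:
                sigma[i] = j
                best -= sub[0, pos]
                free_cols.pop(pos)
                sub = np.delete(np.delete(sub, 0, axis=0), pos, axis=1)
                break
        else:  # pragma: no cover - defensive, cannot happen for finite scores
            raise RuntimeError("no consistent assignment found")
    return sigma


def build_tracks(label_movie: LabelVolume, frame_interval: float,
                 epsilon: float = 0.33) -> tuple[TrackTable, LabelVolume]:
    """Chain per-step assignments into stable track labels.

    Returns the kinematic table plus a relabelled copy of the movie in
    which every entity keeps its frame-0 label throughout.
    """
    labels0, centers0 = segment_centers(label_movie.frame(0), label_movie.voxel_size_zyx)
    c = len(labels0)
    T = label_movie.n_frames
    out = np.zeros_like(label_movie.labels)
    out[0] = label_movie.frame(0)
    all_centers = np.empty((T, c, 3))
    all_centers[0] = centers0
    prev_frame = label_movie.frame(0)
    track_labels = list(labels0)
    for t in range(T - 1):
        nxt = label_movie.frame(t + 1)
        n_next = len(np.unique(nxt)) - (1 if (nxt == 0).any() else 0)
        if n_next != c:
            raise ValidationError(
                f"frame {t + 1} has {n_next} segments, expected {c}")
        conf = tracking_confidence(prev_frame, nxt, label_movie.voxel_size_zyx, epsilon)
        sigma = assign_tracks(conf)
        relabel = np.zeros(int(conf.labels_t1.max()) + 1, dtype=out.dtype)
        for i, lab in enumerate(conf.labels_t):
            relabel[conf.labels_t1[sigma[i]]] = lab
        out[t + 1] = relabel[nxt]
        labs, centers = segment_centers(out[t + 1], label_movie.voxel_size_zyx)
        order = {lab: i for i, lab in enumerate(labs)}
        all_centers[t + 1] = centers[[order[lab] for lab in track_labels]]
        prev_frame = out[t + 1]
    table = TrackTable(
        centers=all_centers,
        labels=[int(lab) for lab in track_labels],
        identity_map=dict(label_movie.identity_map),
        frame_interval=frame_interval,
    )
    stable = LabelVolume(labels=out, identity_map=dict(label_movie.identity_map),
                         kind=label_movie.kind, voxel_size_zyx=label_movie.voxel_size_zyx)
    return table, stable
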