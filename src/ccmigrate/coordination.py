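"""Collective-motion order parameters and neighbour-exchange detection.

Two scalars summarize cluster coordination per frame:

* group polarization ``P(t) = |sum_k d_k| / K`` — how aligned the unit
  movement directions are (1 for coherent translation, the running
  mode);
* angular momentum ``M(t) = |sum_k r_k x d_k| / K`` — how coherently
  the members orbit the cluster center (1 for rigid equatorial
  rotation, the rotating mode), with ``r_k`` the unit vector from the
  cluster center to member ``k``.

A two-class bivariate-Gaussian classifier over ``(P, M)`` separates
the running and rotating modes; its decision boundary is the
equal-posterior locus, and the reported posterior keeps the continuum
of intermediate behaviours visible.

Neighbour exchange — a border cell sliding past others to swap its
relative position — leaves a distance-matrix fingerprint: the temporal
topology change metric ``g(t, s) = max_ij |D(t+s) - D(t)|_ij`` over
pairwise center distances is invariant to rigid cluster motion but
spikes when two members swap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import multivariate_normal

from .model import ValidationError
from .tracking import TrackTable

logger = logging.getLogger(__name__)

Mode = str  # "running" | "rotating"


def group_polarization(directions: np.ndarray) -> float:
    """``P = |sum d_k| / K`` over the K valid (non-NaN) unit directions.

    Returns NaN (undefined-frame flag) if no valid direction remains.
    """
    d = np.asarray(directions, dtype=float).reshape(-1, 3)
    valid = ~np.isnan(d).any(axis=1)
    d = d[valid]
    if d.shape[0] == 0:
        return float("nan")
    return float(np.linalg.norm(d.sum(axis=0)) / d.shape[0])


def angular_momentum(directions: np.ndarray, centers: np.ndarray,
                     cluster_center: np.ndarray) -> float:
    """``M = |sum r_k x d_k| / K`` with unit radius vectors ``r_k``.

    Members with undefined direction or coincident with the cluster
    center are skipped (K reduced); NaN if none remain.
    """
    d = np.asarray(directions, dtype=float).reshape(-1, 3)
    c = np.asarray(centers, dtype=float).reshape(-1, 3)
    cm = np.asarray(cluster_center, dtype=float)
    r = c - cm
    norms = np.linalg.norm(r, axis=1)
    valid = (norms > 0) & ~np.isnan(d).any(axis=1)
    if norms.shape[0] and (norms == 0).any():
        logger.warning("skipping %d member(s) coincident with the cluster center",
                       int((norms == 0).sum()))
    if not valid.any():
        return float("nan")
    r_hat = r[valid] / norms[valid, None]
    cross = np.cross(r_hat, d[valid])
    return float(np.linalg.norm(cross.sum(axis=0)) / valid.sum())


@dataclass
class CoordinationSeries:
    """Per-frame order parameters, mode calls and polar-axis kinematics."""

    polarization: np.ndarray
    momentum: np.ndarray
    cluster_centers: np.ndarray
    modes: list[str] = field(default_factory=list)
    posteriors: np.ndarray | None = None
    axis_directions: np.ndarray | None = None
    axis_step_deg: np.ndarray | None = None
    axis_step_smooth_deg: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        T = len(self.polarization)
        out = {"frame": np.arange(T), "P": self.polarization, "M": self.momentum}
        if self.modes:
            out["mode"] = self.modes + [""] * (T - len(self.modes))
        if self.posteriors is not None:
            out["posterior"] = np.append(self.posteriors,
                                         [np.nan] * (T - len(self.posteriors)))
        if self.axis_step_deg is not None:
            out["axis_step_deg"] = np.append(self.axis_step_deg,
                                             [np.nan] * (T - len(self.axis_step_deg)))
            out["axis_step_smooth_deg"] = np.append(
                self.axis_step_smooth_deg,
                [np.nan] * (T - len(self.axis_step_smooth_deg)))
        return pd.DataFrame(out)


def coordination_series(tracks: TrackTable, members: str = "all") -> CoordinationSeries:
    """P(t) and M(t) per frame transition from a track table.

    ``members`` restricts the computation to one identity ("border",
    "polar") or uses every tracked entity ("all").
    """
    table = tracks if members == "all" else tracks.select(members)
    T = table.n_frames
    P = np.empty(T - 1)
    M = np.empty(T - 1)
    cm = table.centers.mean(axis=1)  # (T, 3)
    for t in range(T - 1):
        P[t] = group_polarization(table.directions[t])
        M[t] = angular_momentum(table.directions[t], table.centers[t], cm[t])
    return CoordinationSeries(polarization=P, momentum=M, cluster_centers=cm)


@dataclass
class ModeClassifier:
    """Bivariate Gaussian per mode over (P, M) with class priors."""

    means: dict[Mode, np.ndarray]
    covariances: dict[Mode, np.ndarray]
    priors: dict[Mode, float]

    def __post_init__(self) -> None:
        if abs(sum(self.priors.values()) - 1.0) > 1e-6:
            raise ValidationError("class priors must sum to 1")
        for mode, cov in self.covariances.items():
            if np.linalg.eigvalsh(np.asarray(cov)).min() <= 0:
                raise ValidationError(f"covariance for {mode!r} not positive-definite")

    def log_joint(self, P: float, M: float) -> dict[Mode, float]:
        x = np.array([P, M])
        return {
            mode: math.log(self.priors[mode])
            + multivariate_normal.logpdf(x, self.means[mode], self.covariances[mode])
            for mode in self.means
        }

    def to_dict(self) -> dict:
        return {
            "means": {k: np.asarray(v).tolist() for k, v in self.means.items()},
            "covariances": {k: np.asarray(v).tolist() for k, v in self.covariances.items()},
            "priors": dict(self.priors),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ModeClassifier":
        return cls(
            means={k: np.asarray(v) for k, v in raw["means"].items()},
            covariances={k: np.asarray(v) for k, v in raw["covariances"].items()},
            priors={k: float(v) for k, v in raw["priors"].items()},
        )


def fit_mode_classifier(samples) -> ModeClassifier:
    """Maximum-likelihood Gaussian per class with frequency priors.

    ``samples`` is an iterable of ``(P, M, mode)``.  A singular class
    covariance receives a 1e-4 ridge with a warning.
    """
    by_mode: dict[str, list] = {}
    for P, M, mode in samples:
        by_mode.setdefault(mode, []).append((P, M))
    if any(len(v) < 2 for v in by_mode.values()) or len(by_mode) < 2:
        raise ValidationError("need >= 2 samples in each of two classes")
    n_total = sum(len(v) for v in by_mode.values())
    means, covs, priors = {}, {}, {}
    for mode, pts in by_mode.items():
        arr = np.asarray(pts, dtype=float)
        means[mode] = arr.mean(axis=0)
        cov = np.cov(arr.T, bias=True)
        if np.linalg.eigvalsh(cov).min() <= 1e-12:
            logger.warning("singular covariance for mode %r; adding ridge", mode)
            cov = cov + 1e-4 * np.eye(2)
        covs[mode] = cov
        priors[mode] = len(pts) / n_total
    return ModeClassifier(means=means, covariances=covs, priors=priors)


def classify_mode(P: float, M: float, clf: ModeClassifier) -> tuple[Mode, float]:
    """Argmax-posterior mode with its posterior probability.

    Exactly on the boundary the call is "running" by convention with
    posterior 0.5.
    """
    log_joint = clf.log_joint(P, M)
    m = max(log_joint.values())
    post = {k: math.exp(v - m) for k, v in log_joint.items()}
    norm = sum(post.values())
    post = {k: v / norm for k, v in post.items()}
    running = post.get("running", 0.0)
    rotating = post.get("rotating", 0.0)
    if running >= rotating:
        return "running", running
    return "rotating", rotating


def default_mode_classifier(seed: int = 0, n_per_class: int = 400,
                            n_members: int = 8) -> ModeClassifier:
    """Classifier trained on simulated (P, M) samples.

    Running frames draw member directions in a cone about a common
    heading; rotating frames draw tangential directions on a ring with
    angular jitter.  The published boundary parameters are not
    available, so this synthetic-trained default ships with the
    package; users can refit on their own annotated frames.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_per_class):
        heading = rng.normal(size=3)
        heading /= np.linalg.norm(heading)
        dirs = heading + 0.35 * rng.normal(size=(n_members, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        centers = rng.normal(size=(n_members, 3))
        samples.append((group_polarization(dirs),
                        angular_momentum(dirs, centers, centers.mean(axis=0)),
                        "running"))
    for _ in range(n_per_class):
        phis = rng.uniform(0, 2 * np.pi, n_members)
        centers = np.stack([np.zeros(n_members), np.sin(phis), np.cos(phis)], axis=1)
        tangents = np.stack([np.zeros(n_members), np.cos(phis), -np.sin(phis)], axis=1)
        dirs = tangents + 0.35 * rng.normal(size=(n_members, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        samples.append((group_polarization(dirs),
                        angular_momentum(dirs, centers, np.zeros(3)),
                        "rotating"))
    return fit_mode_classifier(samples)


def polar_axis_series(polar_centers: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polar-axis directions, per-step rotation angles and their 5-point
    moving average.

    ``polar_centers`` is ``(T, 2, 3)``.  The axis is the normalized
    center difference, undirected, so the step angle is
    ``arccos |a_t . a_{t+1}|`` in degrees.  Coincident polar centers
    flag the frame with a NaN axis.
    """
    pc = np.asarray(polar_centers, dtype=float)
    if pc.ndim != 3 or pc.shape[1] != 2:
        raise ValidationError(f"polar centers must be (T, 2, 3), got {pc.shape}")
    diff = pc[:, 0] - pc[:, 1]
    norms = np.linalg.norm(diff, axis=1)
    axes = np.full_like(diff, np.nan)
    ok = norms > 0
    axes[ok] = diff[ok] / norms[ok, None]
    dots = np.abs(np.einsum("ij,ij->i", axes[:-1], axes[1:]))
    angles = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    smooth = moving_average(angles, 5)
    return axes, angles, smooth


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrunken windows at the ends."""
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        seg = x[lo:hi]
        seg = seg[~np.isnan(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out


@dataclass
class ExchangeScaleSpace:
    """Temporal topology change metric over (time, step) scale space."""

    g: np.ndarray                    # (T, max_step + 1), NaN outside range
    argmax_pairs: np.ndarray         # (T, max_step + 1, 2) member indices
    frame_interval: float
    labels: list[int]


@dataclass(frozen=True)
class ExchangeEventRecord:
    frame: int
    duration_min: float
    pair: tuple[int, int]
    magnitude_um: float


def exchange_metric(centers: np.ndarray, max_step: int,
                    frame_interval: float = 1.0,
                    labels=None) -> ExchangeScaleSpace:
    """``g(t, s) = max_ij |D(t+s) - D(t)|_ij`` for s = 1..max_step."""
    centers = np.asarray(centers, dtype=float)
    T, K, _ = centers.shape
    if K < 2:
        raise ValidationError("exchange metric needs at least 2 members")
    if max_step >= T:
        raise ValidationError("max_step must be smaller than the frame count")
    D = np.stack([squareform(pdist(centers[t])) for t in range(T)])
    g = np.full((T, max_step + 1), np.nan)
    arg = np.zeros((T, max_step + 1, 2), dtype=int)
    g[:, 0] = 0.0
    iu = np.triu_indices(K, k=1)
    for s in range(1, max_step + 1):
        for t in range(T - s):
            diff = np.abs(D[t + s] - D[t])[iu]
            j = int(np.argmax(diff))
            g[t, s] = diff[j]
            arg[t, s] = (iu[0][j], iu[1][j])
    if labels is None:
        labels = list(range(1, K + 1))
    return ExchangeScaleSpace(g=g, argmax_pairs=arg,
                              frame_interval=frame_interval, labels=list(labels))


def detect_exchanges(space: ExchangeScaleSpace, tau_um: float
                     ) -> list[ExchangeEventRecord]:
    """One event per super-threshold blob of the scale space.

    The region ``g > tau`` is split into connected components (the hot
    spots of the scale-space heat map); a rigid-motion background keeps
    ``g`` near zero, so each component corresponds to one exchange.
    The finest scale then localizes each event: over the component's
    time span, the single-step row ``g(t, 1)`` is quiet outside the
    exchange and active throughout it, so the event time is the first
    active step and the duration the active extent.  The implicated
    pair is the argmax distance-matrix entry at the event onset.
    """
    if tau_um <= 0:
        raise ValidationError("tau must be > 0")
    g = space.g
    hot = np.nan_to_num(g, nan=0.0) > tau_um
    hot[:, 0] = False
    labelled, n = ndimage.label(hot, structure=np.ones((3, 3), dtype=bool))
    events = []
    for comp in range(1, n + 1):
        ts, ss = np.nonzero(labelled == comp)
        lo = int(ts.min())
        hi = int((ts + ss).max())
        step_row = np.nan_to_num(g[lo:hi + 1, 1], nan=0.0)
        peak = step_row.max()
        support = np.flatnonzero(step_row >= 0.3 * peak) if peak > 0 else np.array([0])
        t_first = lo + int(support.min())
        duration = (int(support.max()) - int(support.min()) + 1) * space.frame_interval
        i, j = space.argmax_pairs[t_first, 1]
        events.append(ExchangeEventRecord(
            frame=t_first, duration_min=duration,
            pair=(space.labels[i], space.labels[j]),
            magnitude_um=float(np.nanmax(g[ts, ss]))))
    return sorted(events, key=lambda e: e.frame)
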