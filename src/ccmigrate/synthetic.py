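"""Ground-truthed synthetic movies of a migrating cell cluster.

The generator emulates the *Drosophila* border-cell cluster: 2 polar
cells at the center surrounded by border cells, packed into a ball,
migrating between large substrate (nurse) cells.  Cell geometry is a
Voronoi partition of the cluster ball seeded by the nucleus centers;
the nuclei channel is a sum of Gaussian blobs, the membrane channel a
thin shell on inter-cell boundaries and the cluster surface, and the
nurse channel a Voronoi foam of substrate seeds.  Photobleaching,
Poisson + Gaussian noise and z-decimation degrade the movie while the
returned ground truth records everything pre-degradation.

Default scales follow the real system: isotropic 0.33 um voxels before
decimation, border-cell volume ~1,250 um^3, nucleus diameter ~5 um, a
cluster of 2 polar + 6 border cells, frame interval 1 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .model import LabelVolume, MovieStack, ValidationError
from .tracking import TrackTable


class ConfigurationError(ValidationError):
    pass


@dataclass(frozen=True)
class MotionSegment:
    """One segment of the motion schedule.

    ``speed`` is um/min for running and chaotic segments and deg/min
    for rotating segments; ``axis`` is the (z, y, x) translation or
    rotation axis; ``drift`` is an optional constant cluster-center
    drift in um/min applied on top of the segment motion.
    """

    mode: Literal["running", "rotating", "chaotic"]
    n_frames: int
    speed: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ExchangeEvent:
    label_a: int
    label_b: int
    start_frame: int
    duration_frames: int


@dataclass(frozen=True)
class ProtrusionEvent:
    owner: int
    direction: tuple[float, float, float]  # (z, y, x), unit vector in the lab frame
    length_um: float
    width_um: float
    start: int
    duration: int


@dataclass
class SceneConfig:
    n_border: int = 6
    cluster_radius_um: float = 12.75
    nucleus_sigma_um: float = 1.25
    motion_schedule: list[MotionSegment] = field(
        default_factory=lambda: [MotionSegment("running", 10, 1.5, (0.0, 0.0, 1.0))]
    )
    exchange_events: list[ExchangeEvent] = field(default_factory=list)
    protrusion_events: list[ProtrusionEvent] = field(default_factory=list)
    bleach_rate: float = 0.02            # per frame, all channels
    noise_gaussian: float = 1.5          # additive sigma, intensity units
    poisson_noise: bool = True
    z_subsample_factor: int = 3
    voxel_um: float = 0.33
    frame_interval_min: float = 1.0
    seed: int = 0
    # intensity model
    nuclei_amp: float = 60.0
    membrane_amp: float = 30.0
    nurse_amp: float = 30.0
    background: float = 2.0
    nurse_seed_spacing_um: float = 18.0
    margin_um: float = 3.0

    def __post_init__(self) -> None:
        if self.n_border < 1:
            raise ConfigurationError("n_border must be >= 1")
        if self.cluster_radius_um <= self.nucleus_sigma_um:
            raise ConfigurationError("cluster radius must exceed nucleus sigma")
        if any(seg.n_frames < 1 for seg in self.motion_schedule):
            raise ConfigurationError("motion segments need n_frames >= 1")
        if any(ev.duration_frames < 1 for ev in self.exchange_events):
            raise ConfigurationError("exchange durations must be >= 1")
        if any(ev.duration < 1 for ev in self.protrusion_events):
            raise ConfigurationError("protrusion durations must be >= 1")
        if self.z_subsample_factor < 1:
            raise ConfigurationError("z_subsample_factor must be >= 1")

    @property
    def n_frames(self) -> int:
        return sum(seg.n_frames for seg in self.motion_schedule) + 1

    @property
    def n_cells(self) -> int:
        return self.n_border + 2


@dataclass
class GroundTruth:
    nuclei_labels: LabelVolume
    cell_labels: LabelVolume
    true_tracks: TrackTable
    event_log: dict
    mode_per_frame: list[str]
    cluster_centers: np.ndarray  # (T, 3) um


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero vector cannot be normalized")
    return v / n


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to v."""
    trial = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, trial))


def initial_positions(cfg: SceneConfig) -> np.ndarray:
    """Cluster-frame nucleus centers: polar pair 1-2 at the center
    (offset along y), border ring 3..c in the z = 0 equatorial plane."""
    # polar pair near the center; border nuclei at ~0.7 R, the centroid
    # radius of a shell-shaped cell spanning polar surface to cluster rim
    polar_offset = 1.8
    ring_radius = 0.7 * cfg.cluster_radius_um
    centers = [np.array([0.0, polar_offset, 0.0]), np.array([0.0, -polar_offset, 0.0])]
    for k in range(cfg.n_border):
        phi = 2.0 * math.pi * k / cfg.n_border
        centers.append(np.array([0.0, ring_radius * math.sin(phi), ring_radius * math.cos(phi)]))
    centers = np.array(centers)
    dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    np.fill_diagonal(dists, np.inf)
    if dists.min() < 2.0 * cfg.nucleus_sigma_um:
        raise ConfigurationError(
            f"initial nuclei closer than 2 sigma ({dists.min():.2f} um)")
    return centers


def _rotation_matrix(axis, angle_rad: float) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(_unit(axis)) * angle_rad).as_matrix()


def inject_exchange(positions: np.ndarray, event: ExchangeEvent,
                    cluster_centers: np.ndarray | None = None) -> np.ndarray:
    """Swap two entities' cluster-frame positions along smooth arcs.

    ``positions`` is ``(T, K, 3)``; entities are indexed by 0-based
    labels-1.  During the event the two centers follow symmetric arcs
    (linear blend plus a perpendicular half-sine bump keeping them
    separated); from the end of the event onwards their cluster-frame
    positions are swapped.  All other relative positions are preserved.
    """
    positions = np.asarray(positions, dtype=float)
    T = positions.shape[0]
    if event.label_a == event.label_b:
        raise ConfigurationError("exchange requires two distinct labels")
    a, b = event.label_a - 1, event.label_b - 1
    if not (0 <= a < positions.shape[1] and 0 <= b < positions.shape[1]):
        raise ConfigurationError("exchange labels outside the position table")
    t0, dur = event.start_frame, event.duration_frames
    if t0 < 0 or t0 + dur >= T:
        raise ConfigurationError("exchange event frames outside the movie")
    if cluster_centers is None:
        cluster_centers = positions.mean(axis=1)
    rel = positions - cluster_centers[:, None, :]
    out = rel.copy()
    ra0, rb0 = rel[t0, a].copy(), rel[t0, b].copy()
    Ra, Rb = np.linalg.norm(ra0), np.linalg.norm(rb0)
    if Ra == 0 or Rb == 0:
        raise ConfigurationError("exchange partners must be off the cluster center")
    ua, ub = ra0 / Ra, rb0 / Rb
    cosphi = float(np.clip(np.dot(ua, ub), -1.0, 1.0))
    phi = math.acos(cosphi)
    if phi > math.pi - 1e-6:  # antipodal: route via an arbitrary waypoint plane
        axis = _perpendicular(ua)
    else:
        axis = _unit(np.cross(ua, ub))
    # the two cells slide over the cluster surface along the same great
    # circle in opposite senses; a small radial separation (one passes
    # outside the other) keeps them apart at mid-arc
    separation = 2.5
    for t in range(t0, t0 + dur + 1):
        u = (t - t0) / dur
        bump = separation * math.sin(math.pi * u)
        dir_a = _rotation_matrix(axis, u * phi) @ ua
        dir_b = _rotation_matrix(axis, -u * phi) @ ub
        out[t, a] = ((1 - u) * Ra + u * Rb + bump) * dir_a
        out[t, b] = ((1 - u) * Rb + u * Ra - bump) * dir_b
    # after the event the two trajectories continue swapped
    for t in range(t0 + dur + 1, T):
        out[t, a], out[t, b] = rel[t, b].copy(), rel[t, a].copy()
    return out + cluster_centers[:, None, :]


def build_trajectories(cfg: SceneConfig, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Absolute center trajectories ``(T, K, 3)`` in um, the cluster
    center path ``(T, 3)`` and the per-frame motion mode."""
    K = cfg.n_cells
    T = cfg.n_frames
    dt = cfg.frame_interval_min
    rel0 = initial_positions(cfg)
    rel = np.empty((T, K, 3))
    rel[0] = rel0
    center = np.zeros((T, 3))
    modes: list[str] = []
    t = 0
    for seg in cfg.motion_schedule:
        axis = _unit(seg.axis)
        drift = np.asarray(seg.drift, dtype=float)
        for _ in range(seg.n_frames):
            modes.append(seg.mode)
            step_rel = rel[t]
            if seg.mode == "running":
                center[t + 1] = center[t] + (seg.speed * axis + drift) * dt
                rel[t + 1] = step_rel
            elif seg.mode == "rotating":
                R = _rotation_matrix(axis, math.radians(seg.speed) * dt)
                center[t + 1] = center[t] + drift * dt
                rel[t + 1] = step_rel @ R.T
            elif seg.mode == "chaotic":
                steps = rng.normal(size=(K, 3))
                steps = steps / np.linalg.norm(steps, axis=1, keepdims=True)
                rel[t + 1] = step_rel + seg.speed * dt * steps
                # soft containment: keep nuclei inside the cluster ball
                norms = np.linalg.norm(rel[t + 1], axis=1)
                limit = cfg.cluster_radius_um - 2.0 * cfg.nucleus_sigma_um
                over = norms > limit
                rel[t + 1][over] *= (limit / norms[over])[:, None]
                center[t + 1] = center[t] + drift * dt
            else:  # pragma: no cover
                raise ConfigurationError(f"unknown motion mode {seg.mode!r}")
            t += 1
    modes.append(modes[-1] if modes else "running")
    positions = center[:, None, :] + rel
    for event in cfg.exchange_events:
        positions = inject_exchange(positions, event, cluster_centers=center)
    return positions, center, modes


def _ball_coords(shape, voxel_um):
    grids = np.meshgrid(*[np.arange(n) * voxel_um for n in shape], indexing="ij")
    return np.stack(grids, axis=-1)  # (Z, Y, X, 3) um


def _protrusion_cylinder(coords_um: np.ndarray, center: np.ndarray,
                         ev: ProtrusionEvent, cluster_radius: float) -> np.ndarray:
    d = _unit(ev.direction)
    p0 = center + d * (cluster_radius - ev.width_um)
    rel = coords_um - p0
    axial = rel @ d
    radial = np.linalg.norm(rel - axial[..., None] * d[None, None, None, :], axis=-1)
    return (axial >= 0) & (axial <= ev.length_um + ev.width_um) & (radial <= ev.width_um / 2.0)


def _boundary_shell(labels: np.ndarray) -> np.ndarray:
    """Voxels of a label image whose 6-neighbourhood crosses a label
    change (including label-to-background): 1-voxel-thick membranes."""
    shell = np.zeros(labels.shape, dtype=bool)
    fg = labels > 0
    for axis in range(3):
        for shift in (1, -1):
            neigh = np.roll(labels, shift, axis=axis)
            # roll wraps; mask out the wrapped border slice
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            differ = neigh != labels
            differ[tuple(edge)] = True
            shell |= fg & differ
    return shell


def generate_movie(cfg: SceneConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a ground-truthed two/three-channel movie from a scene."""
    rng = np.random.default_rng(cfg.seed)
    positions, center_path, modes = build_trajectories(cfg, rng)
    T, K, _ = positions.shape
    vox = cfg.voxel_um
    max_prot = max([ev.length_um for ev in cfg.protrusion_events], default=0.0)
    pad = cfg.cluster_radius_um + max_prot + cfg.margin_um
    lo = positions.reshape(-1, 3).min(axis=0) - pad
    hi = positions.reshape(-1, 3).max(axis=0) + pad
    origin = lo
    shape = tuple(int(math.ceil(e / vox)) + 1 for e in (hi - lo))
    # work in box coordinates so tracks and label volumes share one frame
    positions = positions - origin
    center_path = center_path - origin
    lo = lo - origin
    hi = hi - origin
    coords = _ball_coords(shape, vox)  # box-frame um coordinates

    # static nurse-cell foam: Voronoi of jittered grid seeds over the box
    from scipy.spatial import cKDTree

    spacing = cfg.nurse_seed_spacing_um
    zs = np.arange(lo[0] - spacing, hi[0] + spacing, spacing)
    ys = np.arange(lo[1] - spacing, hi[1] + spacing, spacing)
    xs = np.arange(lo[2] - spacing, hi[2] + spacing, spacing)
    grid = np.array([[z, y, x] for z in zs for y in ys for x in xs])
    seeds = grid + rng.uniform(-0.25 * spacing, 0.25 * spacing, grid.shape)
    nearest = cKDTree(seeds).query(coords.reshape(-1, 3), workers=-1)[1]
    nurse_labels = nearest.reshape(shape).astype(np.int32) + 1
    nurse_shell = _boundary_shell(nurse_labels)

    nuclei_radius = 2.0 * cfg.nucleus_sigma_um
    cell_labels = np.zeros((T,) + shape, dtype=np.int16)
    nuc_labels = np.zeros((T,) + shape, dtype=np.int16)
    nuclei_chan = np.zeros((T,) + shape, dtype=np.float32)
    membrane_chan = np.zeros((T,) + shape, dtype=np.float32)
    nurse_chan = np.zeros((T,) + shape, dtype=np.float32)

    sub_pad = cfg.cluster_radius_um + max_prot + 1.5
    for t in range(T):
        c = center_path[t]
        # render inside a sub-box around the cluster; outside it only the
        # static nurse foam contributes
        lo_v = np.maximum(0, np.floor((c - sub_pad) / vox).astype(int))
        hi_v = np.minimum(shape, np.ceil((c + sub_pad) / vox).astype(int) + 1)
        sub = tuple(slice(a, b) for a, b in zip(lo_v, hi_v))
        sc = coords[sub]
        dist_c = np.linalg.norm(sc - c, axis=-1)
        mask = dist_c <= cfg.cluster_radius_um
        # Voronoi partition of the ball by nucleus centers
        dists = np.stack([np.linalg.norm(sc - positions[t, k], axis=-1)
                          for k in range(K)])
        vor = np.argmin(dists, axis=0).astype(np.int16) + 1
        frame_cells = np.where(mask, vor, 0).astype(np.int16)
        for ev in cfg.protrusion_events:
            if ev.start <= t < ev.start + ev.duration:
                cyl = _protrusion_cylinder(sc, c, ev, cfg.cluster_radius_um)
                frame_cells[cyl] = ev.owner
        cell_labels[t][sub] = frame_cells
        near = np.min(dists, axis=0)
        nuc_labels[t][sub] = np.where(near <= nuclei_radius, vor, 0)
        blob = np.zeros(sc.shape[:3], dtype=np.float32)
        for k in range(K):
            blob += cfg.nuclei_amp * np.exp(
                -0.5 * (dists[k] / cfg.nucleus_sigma_um) ** 2).astype(np.float32)
        nuclei_chan[t][sub] = blob
        membrane_chan[t][sub] = cfg.membrane_amp * _boundary_shell(frame_cells)
        nurse_chan[t] = cfg.nurse_amp * (nurse_shell & (cell_labels[t] == 0))

    identity_map = {k + 1: ("polar" if k < 2 else "border") for k in range(K)}
    tracks = TrackTable(centers=positions, labels=list(range(1, K + 1)),
                        identity_map=identity_map,
                        frame_interval=cfg.frame_interval_min)
    truth = GroundTruth(
        nuclei_labels=LabelVolume(labels=nuc_labels, identity_map=identity_map,
                                  kind="nuclei", voxel_size_zyx=(vox, vox, vox)),
        cell_labels=LabelVolume(labels=cell_labels, identity_map=identity_map,
                                kind="cells", voxel_size_zyx=(vox, vox, vox)),
        true_tracks=tracks,
        event_log={
            "exchanges": [vars(ev) if not hasattr(ev, "__dataclass_fields__")
                          else {f: getattr(ev, f) for f in ev.__dataclass_fields__}
                          for ev in cfg.exchange_events],
            "protrusions": [{f: getattr(ev, f) for f in ev.__dataclass_fields__}
                            for ev in cfg.protrusion_events],
        },
        mode_per_frame=modes,
        cluster_centers=center_path,
    )

    k = cfg.z_subsample_factor
    data = np.stack([nuclei_chan[:, ::k], membrane_chan[:, ::k],
                     nurse_chan[:, ::k]], axis=1)
    data += cfg.background
    bleach = np.exp(-cfg.bleach_rate * np.arange(T, dtype=np.float32))
    data *= bleach[:, None, None, None, None]
    for t in range(T):  # frame-wise to bound the noise working memory
        frame = data[t]
        if cfg.poisson_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(np.float32)
        if cfg.noise_gaussian > 0:
            frame = frame + rng.normal(0.0, cfg.noise_gaussian,
                                       frame.shape).astype(np.float32)
        data[t] = np.clip(frame, 0, None)
    movie = MovieStack(
        data=data,
        channel_names=("nuclei", "cell_membrane", "nurse_membrane"),
        voxel_size_zyx=(vox * k, vox, vox),
        frame_interval=cfg.frame_interval_min,
    )
    return movie, truth


def annotation_dataframe(truth: GroundTruth, movie: MovieStack):
    """Frame-0 annotation rows (voxel coordinates of the degraded movie)
    derived from the ground-truth tracks."""
    import pandas as pd

    vox = np.asarray(movie.voxel_size_zyx)
    rows = []
    for k, lab in enumerate(truth.true_tracks.labels):
        zyx_um = truth.true_tracks.centers[0, k]
        rows.append({
            "z": zyx_um[0] / vox[0], "y": zyx_um[1] / vox[1],
            "x": zyx_um[2] / vox[2],
            "identity": truth.true_tracks.identity_map[lab],
        })
    return pd.DataFrame(rows)
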