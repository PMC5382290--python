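"""Canonical synthetic evaluation scenarios.

Each function builds a ground-truthed scene at the scales of the real
border-cell system, runs the relevant part of the pipeline, and
returns the headline statistic.  They are used both by the test suite
and by the reproduction script, so the numbers reported anywhere are
always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from . import pipeline as pipe
from . import protrusion as prot
from .coordination import detect_exchanges, exchange_metric
from .io import read_annotation
from .model import PipelineConfig
from .synthetic import (
    ExchangeEvent,
    MotionSegment,
    ProtrusionEvent,
    SceneConfig,
    build_trajectories,
    generate_movie,
)

EXCHANGE_TAU_UM = 30 * 0.33  # twice the mean nucleus diameter


def _cone_direction(rng: np.random.Generator, axis, max_deg: float) -> tuple:
    """Unit vector uniform on the spherical cap within ``max_deg`` of axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos_max = np.cos(np.radians(max_deg))
    c = rng.uniform(cos_max, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - c * c)
    # orthonormal frame around the axis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return tuple(c * axis + s * (np.cos(phi) * e1 + np.sin(phi) * e2))


def running_protrusion_alignment(seed: int, n_frames: int = 20) -> float:
    """Mean PA on a running movie whose protrusions lie within 30 deg of
    the migration direction."""
    rng = np.random.default_rng(seed)
    axis = (0.0, 0.0, 1.0)
    events = [ProtrusionEvent(owner=3, direction=_cone_direction(rng, axis, 30.0),
                              length_um=8.0, width_um=3.0, start=t, duration=1)
              for t in range(n_frames)]
    cfg = SceneConfig(motion_schedule=[MotionSegment("running", n_frames, 1.5, axis)],
                      protrusion_events=events, seed=seed)
    _, truth = generate_movie(cfg)
    return _mean_pa(truth)


def rotating_protrusion_alignment(seed: int, n_frames: int = 20) -> float:
    """Mean PA on a slowly drifting rotating movie whose protrusions are
    tangential (perpendicular to the drift, jittered up to 10 deg)."""
    rng = np.random.default_rng(seed)
    drift = (0.0, 0.0, 0.5)
    events = []
    for t in range(n_frames):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        tangential = np.array([np.sin(phi), np.cos(phi), 0.0])  # perpendicular to x drift
        events.append(ProtrusionEvent(owner=3,
                                      direction=_cone_direction(rng, tangential, 10.0),
                                      length_um=8.0, width_um=3.0, start=t, duration=1))
    cfg = SceneConfig(
        motion_schedule=[MotionSegment("rotating", n_frames, 5.0, (1.0, 0.0, 0.0),
                                       drift=drift)],
        protrusion_events=events, seed=seed)
    _, truth = generate_movie(cfg)
    return _mean_pa(truth)


def _mean_pa(truth) -> float:
    masks = truth.cell_labels.labels > 0
    voxel = truth.cell_labels.voxel_size_zyx[0]
    records, velocity = prot.analyse_protrusions(
        masks, truth.cell_labels.labels, 1250.0, voxel,
        truth.true_tracks.frame_interval)
    dirs = np.array([r.direction if r.direction is not None else (np.nan,) * 3
                     for r in records])
    _, mean_pa = prot.protrusion_alignment(dirs[:-1], velocity)
    return mean_pa


def rotating_deformation_angle(seed: int, n_frames: int = 20) -> float:
    """Movie-mean angle between the combined cluster rotating vector and
    the combined protrusion rotating vector on an equatorial rigid
    rotation driven by tangential cell extensions."""
    cfg = SceneConfig(
        motion_schedule=[MotionSegment("rotating", n_frames, 5.0, (1.0, 0.0, 0.0))],
        seed=seed)
    _, truth = generate_movie(cfg)
    voxel = truth.cell_labels.voxel_size_zyx[0]
    fields = prot.deformation_fields(truth.cell_labels.labels, voxel)
    assoc = prot.rotation_association(truth.true_tracks, fields,
                                      truth.cluster_centers)
    return assoc.mean_angle_deg


def full_pipeline_tpr(seed: int, n_frames: int = 10) -> float:
    """Voxel-level cell-segmentation true positive rate of the full
    pipeline (preprocess, GMM nuclei, tracking, volume-constrained
    watershed) against ground truth on a default-noise movie."""
    import tempfile
    from pathlib import Path

    from .synthetic import annotation_dataframe

    cfg = SceneConfig(
        motion_schedule=[MotionSegment("running", n_frames - 1, 1.5, (0.0, 0.0, 1.0))],
        seed=seed)
    movie, truth = generate_movie(cfg)
    with tempfile.TemporaryDirectory() as tmp:
        ann_path = Path(tmp) / "annotation.csv"
        annotation_dataframe(truth, movie).to_csv(ann_path, index=False)
        annotation = read_annotation(ann_path, movie.frame_shape)
    seg = pipe.segment_and_track(movie, annotation, PipelineConfig())
    return pipe.cell_segmentation_tpr(seg.cell_labels, truth)


def exchange_recall(n_scenes: int = 20, base_seed: int = 0
                    ) -> tuple[float, float, float]:
    """Recall plus worst-case timing errors of neighbour-exchange
    detection over seeded scenes.

    Each scene is an 8-border-cell cluster running at 1.5 um/min with
    one diametric position swap of random onset and duration; returns
    (recall, max |frame error|, max |duration error|) over detected
    events matched to injections.
    """
    hits = 0
    max_dt = 0.0
    max_dd = 0.0
    for i in range(n_scenes):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        T = 30
        f = int(rng.integers(8, 18))
        d = int(rng.integers(3, 7))
        a = 3 + int(rng.integers(0, 8))
        b = 3 + (a - 3 + 4) % 8
        cfg = SceneConfig(
            n_border=8, cluster_radius_um=13.9,
            motion_schedule=[MotionSegment("running", T, 1.5, (0.0, 0.0, 1.0))],
            exchange_events=[ExchangeEvent(a, b, f, d)], seed=seed)
        positions, _, _ = build_trajectories(cfg, rng)
        space = exchange_metric(positions, max_step=10, frame_interval=1.0)
        events = detect_exchanges(space, EXCHANGE_TAU_UM)
        matched = [e for e in events
                   if abs(e.frame - f) <= 1 and abs(e.duration_min - d) <= 1]
        if matched and len(events) == 1:
            hits += 1
            max_dt = max(max_dt, abs(matched[0].frame - f))
            max_dd = max(max_dd, abs(matched[0].duration_min - d))
    return hits / n_scenes, max_dt, max_dd
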