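"""End-to-end orchestration: movie in, per-cell quantification out.

Stages communicate only via in-memory arrays here and via TIFF/CSV
files in the command-line wrapper, so any stage can be re-run and
tested in isolation.  The chain is: preprocess -> GMM nuclei ->
tracking -> volume-constrained watershed cells -> coordination ->
protrusions -> deformation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cells as cellseg
from . import coordination as coord
from . import nuclei as nucseg
from . import preprocess as prep
from . import protrusion as prot
from . import tracking
from .model import Annotation, AnnotationEntry, LabelVolume, MovieStack, PipelineConfig
from .synthetic import GroundTruth

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    movie: MovieStack                 # preprocessed, isotropic
    bleach_report: prep.BleachReport
    nuclei_labels: LabelVolume
    cell_labels: LabelVolume
    cluster_masks: np.ndarray         # (T, Z, Y, X) bool
    nuclei_tracks: tracking.TrackTable
    cell_tracks: tracking.TrackTable


def rescale_annotation(annotation: Annotation, raw_voxel_zyx,
                       target_um: float) -> Annotation:
    """Convert annotation voxel coordinates from the raw grid to the
    isotropically resampled grid."""
    scale = np.asarray(raw_voxel_zyx, dtype=float) / target_um
    entries = [
        AnnotationEntry(center_zyx=tuple(np.asarray(e.center_zyx) * scale),
                        identity=e.identity, label=e.label)
        for e in annotation.entries
    ]
    return Annotation(entries=entries)


def segment_and_track(movie: MovieStack, annotation: Annotation,
                      config: PipelineConfig) -> SegmentationResult:
    """Run preprocessing, nucleus GMM segmentation, tracking and
    volume-constrained watershed cell segmentation on a raw movie."""
    t0 = time.perf_counter()
    iso_annotation = rescale_annotation(annotation, movie.voxel_size_zyx,
                                        config.target_voxel_um)
    clean, bleach_report = prep.preprocess(
        movie, target_um=config.target_voxel_um,
        sigma_um=config.gaussian_sigma_um,
        bg_radius_um=config.background_radius_um,
        background_level=config.background_level)
    voxel = clean.voxel_size_zyx
    logger.info("preprocess done in %.1fs", time.perf_counter() - t0)

    gmm_cfg = nucseg.GMMConfig(alpha=config.gmm_alpha, reg_um2=config.gmm_reg_um2,
                               tol=config.gmm_tol, max_iter=config.gmm_max_iter,
                               kappa=config.laplacian_kappa,
                               min_component_um3=config.min_component_um3)
    nuclei_stack = clean.channel("nuclei")
    nuc_label_arr, _ = nucseg.segment_movie_nuclei(nuclei_stack, iso_annotation,
                                                   gmm_cfg, voxel)
    nuclei_labels = LabelVolume(labels=nuc_label_arr,
                                identity_map=iso_annotation.identity_map,
                                kind="nuclei", voxel_size_zyx=voxel)
    logger.info("nuclei segmented in %.1fs", time.perf_counter() - t0)

    nuclei_tracks, nuclei_labels = tracking.build_tracks(
        nuclei_labels, clean.frame_interval, epsilon=config.tracking_epsilon_um)

    n_border = sum(1 for i in iso_annotation.identity_map.values() if i == "border")
    v_target = cellseg.target_cluster_volume(
        n_border, config.border_volume_um3, config.polar_volume_um3)
    kernel_cfg = cellseg.MembraneKernelConfig(
        sigma_um=config.membrane_sigma_um,
        angle_step_deg=config.membrane_angle_step_deg)
    membrane = clean.channel("cell_membrane")
    T = clean.n_frames
    cluster_masks = np.zeros((T,) + clean.frame_shape, dtype=bool)
    cell_arr = np.zeros((T,) + clean.frame_shape, dtype=np.int32)
    for t in range(T):
        combined = membrane[t] + nuclei_stack[t]
        mask = cellseg.cluster_mask(combined, v_target, voxel)
        mask |= nuclei_labels.frame(t) > 0  # nuclei are inside the cluster
        enhanced = cellseg.enhance_membrane(membrane[t], kernel_cfg, voxel)
        cell_arr[t] = cellseg.watershed_cells(enhanced, nuclei_labels.frame(t), mask)
        cluster_masks[t] = mask
    cell_labels = LabelVolume(labels=cell_arr,
                              identity_map=iso_annotation.identity_map,
                              kind="cells", voxel_size_zyx=voxel)
    cell_tracks, cell_labels = tracking.build_tracks(
        cell_labels, clean.frame_interval, epsilon=config.tracking_epsilon_um)
    logger.info("cells segmented in %.1fs", time.perf_counter() - t0)
    return SegmentationResult(movie=clean, bleach_report=bleach_report,
                              nuclei_labels=nuclei_labels,
                              cell_labels=cell_labels,
                              cluster_masks=cluster_masks,
                              nuclei_tracks=nuclei_tracks,
                              cell_tracks=cell_tracks)


def quantify(seg: SegmentationResult, config: PipelineConfig) -> dict:
    """Coordination, interface, exchange, protrusion and deformation
    tables from a segmentation result."""
    voxel_um = config.target_voxel_um
    series = coord.coordination_series(seg.nuclei_tracks)
    clf = coord.default_mode_classifier(seed=config.seed)
    modes, posts = [], []
    for P, M in zip(series.polarization, series.momentum):
        mode, post = coord.classify_mode(P, M, clf)
        modes.append(mode)
        posts.append(post)
    series.modes = modes
    series.posteriors = np.asarray(posts)
    polar = seg.nuclei_tracks.select("polar")
    axes, steps, smooth = coord.polar_axis_series(
        polar.centers.reshape(polar.n_frames, 2, 3))
    series.axis_directions = axes
    series.axis_step_deg = steps
    series.axis_step_smooth_deg = smooth

    space = coord.exchange_metric(seg.nuclei_tracks.centers,
                                  max_step=min(config.exchange_max_step,
                                               seg.nuclei_tracks.n_frames - 1),
                                  frame_interval=seg.movie.frame_interval,
                                  labels=seg.nuclei_tracks.labels)
    exchanges = coord.detect_exchanges(space, config.exchange_tau_um)

    records, body_velocity = prot.analyse_protrusions(
        seg.cluster_masks, seg.cell_labels.labels,
        config.border_volume_um3, voxel_um, seg.movie.frame_interval)
    fields = prot.deformation_fields(seg.cell_labels.labels, voxel_um)
    if len(records) >= 4:
        cd, cs = prot.protrusion_coupling(records, body_velocity, voxel_um)
    else:
        cd, cs = float("nan"), float("nan")
    mobility = prot.mobility_params(seg.nuclei_tracks, seg.cell_tracks, fields)
    if len(fields) >= 3:
        association = prot.rotation_association(seg.nuclei_tracks, fields,
                                                series.cluster_centers)
    else:
        logger.warning("movie too short for rotation association (< 3 frame pairs)")
        association = None
    interfaces = pd.concat([
        cellseg.cell_interfaces(seg.cell_labels.frame(t), seg.cluster_masks[t],
                                seg.movie.voxel_size_zyx, frame=t).to_dataframe()
        for t in range(seg.cell_labels.n_frames)
    ], ignore_index=True)
    return {
        "coordination": series,
        "exchange_space": space,
        "exchanges": exchanges,
        "protrusions": records,
        "body_velocity": body_velocity,
        "protrusion_cd": cd,
        "protrusion_cs": cs,
        "deformation_fields": fields,
        "mobility": mobility,
        "rotation_association": association,
        "interfaces": interfaces,
    }


def cell_segmentation_tpr(cell_labels: LabelVolume, truth: GroundTruth) -> float:
    """Voxel-level true positive rate of segmented cells vs ground truth.

    Segmented labels are resampled (nearest neighbour) onto the
    ground-truth grid; each ground-truth cell is matched to the
    segmented label with maximal overlap, and the TPR is the fraction
    of ground-truth voxels carrying the matched label, averaged over
    cells and frames.
    """
    from scipy import ndimage

    gt = truth.cell_labels.labels
    seg = cell_labels.labels
    rates = []
    for t in range(gt.shape[0]):
        seg_t = seg[t]
        if seg_t.shape != gt.shape[1:]:
            zoom = [g / s for g, s in zip(gt.shape[1:], seg_t.shape)]
            seg_t = ndimage.zoom(seg_t, zoom, order=0, grid_mode=True,
                                 mode="nearest")
        for lab in np.unique(gt[t]):
            if lab == 0:
                continue
            gt_mask = gt[t] == lab
            inside = seg_t[gt_mask]
            inside = inside[inside > 0]
            if inside.size == 0:
                rates.append(0.0)
                continue
            match = np.bincount(inside).argmax()
            rates.append(float((seg_t[gt_mask] == match).sum() / gt_mask.sum()))
    return float(np.mean(rates))
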