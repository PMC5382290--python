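"""Opening-based protrusion detection, alignment statistics and
surface-deformation mapping."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import ball as skiball

from ccmigrate.model import ValidationError
from ccmigrate.protrusion import (
    ConfigurationError,
    deformation_map,
    detect_protrusion,
    mobility_params,
    pearson,
    protrusion_alignment,
    protrusion_stats,
    rotation_association,
    sphere_radius_from_volume,
)
from ccmigrate.morphology import ball_opening
from ccmigrate.tracking import TrackTable


def ball_mask(shape, center, radius):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


def finger_mask(shape, start, length, half_width, axis=2):
    out = np.zeros(shape, dtype=bool)
    c = [slice(s - half_width, s + half_width + 1) for s in start]
    c[axis] = slice(start[axis], start[axis] + length)
    out[tuple(c)] = True
    return out


class TestDetectProtrusion:
    def test_ball_larger_than_element_leaves_no_residue(self):
        mask = ball_mask((40, 40, 40), (20, 20, 20), 15)
        prot = detect_protrusion(mask, r_um=8.0, voxel_um=1.0)
        assert prot.sum() / mask.sum() < 0.01  # voxelization residue only

    def test_thin_finger_is_isolated(self):
        body = ball_mask((50, 50, 70), (25, 25, 25), 15)
        finger = finger_mask((50, 50, 70), (25, 25, 38), 20, 3)
        prot = detect_protrusion(body | finger, r_um=10.0, voxel_um=1.0)
        outside = finger & ~body
        jaccard = (prot & outside).sum() / (prot | outside).sum()
        assert jaccard >= 0.8

    def test_opening_matches_scipy_composition_oracle(self):
        rng = np.random.default_rng(0)
        mask = ndimage.binary_dilation(rng.random((24, 24, 24)) > 0.97,
                                       iterations=3)
        for r in (2, 3, 4):
            mine = ball_opening(mask, r)
            element = skiball(r)
            oracle = ndimage.binary_dilation(
                ndimage.binary_erosion(mask, structure=element, border_value=0),
                structure=element)
            np.testing.assert_array_equal(mine, oracle)

    def test_anti_extensive(self):
        mask = ball_mask((30, 30, 30), (15, 15, 15), 10) \
            | finger_mask((30, 30, 30), (15, 15, 24), 5, 2)
        prot = detect_protrusion(mask, r_um=6.0, voxel_um=1.0)
        assert (prot & ~mask).sum() == 0

    def test_subvoxel_radius_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_protrusion(np.ones((5, 5, 5), bool), r_um=0.1, voxel_um=0.33)

    def test_sphere_radius_formula(self):
        assert sphere_radius_from_volume(4.0 / 3.0 * np.pi * 27.0) \
            == pytest.approx(3.0)


class TestProtrusionStats:
    def test_finger_direction_is_plus_x(self):
        shape = (40, 40, 60)
        body = ball_mask(shape, (20, 20, 25), 12)
        finger = finger_mask(shape, (20, 20, 36), 15, 2)
        cells = np.where(body | finger, 3, 0)
        prot = detect_protrusion(body | finger, r_um=8.0, voxel_um=1.0)
        rec = protrusion_stats(prot, cells, body | finger, voxel_um=1.0,
                               frame_interval=1.0)
        assert rec.direction is not None
        np.testing.assert_allclose(rec.direction, [0, 0, 1.0], atol=0.1)
        assert rec.owner == 3
        assert rec.rate_um3_min == pytest.approx(rec.volume_um3)

    def test_antipodal_fingers_yield_null_direction(self):
        shape = (40, 40, 80)
        body = ball_mask(shape, (20, 20, 40), 12)
        f1 = finger_mask(shape, (20, 20, 52), 16, 2)   # +x, symmetric pair
        f2 = finger_mask(shape, (20, 20, 13), 16, 2)   # -x
        mask = body | f1 | f2
        prot = detect_protrusion(mask, r_um=8.0, voxel_um=1.0)
        rec = protrusion_stats(prot, np.where(mask, 1, 0), mask, 1.0, 1.0)
        assert rec.direction is None

    def test_empty_protrusion_record(self):
        body = ball_mask((30, 30, 30), (15, 15, 15), 10)
        rec = protrusion_stats(np.zeros_like(body), np.where(body, 1, 0),
                               body, 1.0, 1.0)
        assert rec.volume_um3 == 0.0 and rec.direction is None


class TestAlignmentAndCorrelation:
    @pytest.mark.parametrize("angle_deg, expected", [(0, 1.0), (180, -1.0),
                                                     (60, 0.5)])
    def test_pa_is_cosine(self, angle_deg, expected):
        a = np.array([[0.0, 0.0, 1.0]])
        rad = np.radians(angle_deg)
        b = np.array([[0.0, np.sin(rad), np.cos(rad)]])
        pa, mean = protrusion_alignment(a, b)
        assert mean == pytest.approx(expected, abs=1e-9)

    def test_pearson_extremes_and_hand_case(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)
        y = np.array([2.0, 1.0, 6.0, 3.0])
        # hand computation of sum((x-mx)(y-my)) / sqrt(ssx * ssy)
        mx, my = 3.0, 3.0
        num = ((x - mx) * (y - my)).sum()
        den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
        assert pearson(x, y) == pytest.approx(num / den)

    def test_protrusion_size_coupling_tracks_speed(self):
        # larger protrusions coincide with faster body motion: CS -> 1
        from ccmigrate.protrusion import ProtrusionRecord, protrusion_coupling

        rng = np.random.default_rng(0)
        T = 7
        records = []
        speeds = np.array([0.5, 2.0, 1.0, 3.0, 0.2, 2.5, 1.5])
        for t in range(T):
            vox = np.zeros((12, 12, 12), dtype=bool)
            size = int(10 * speeds[t]) + 1
            vox.flat[:size] = True
            records.append(ProtrusionRecord(
                frame=t, volume_um3=float(100 * speeds[t]),
                rate_um3_min=0.0, direction=None, owner=1,
                body_center_um=np.zeros(3), voxels=vox))
        velocity = np.zeros((T - 1, 3))
        velocity[:, 2] = speeds[:-1]
        cd, cs = protrusion_coupling(records, velocity)
        assert cs == pytest.approx(1.0)
        assert -1.0 <= cd <= 1.0 or np.isnan(cd)

    def test_pearson_needs_variance_and_samples(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError):
            pearson([1.0, 2.0], [3.0, 4.0])


class TestDeformationMap:
    def test_identical_sets_have_no_samples(self):
        cell = ball_mask((20, 20, 20), (10, 10, 10), 6)
        entry = deformation_map(cell, cell, voxel_um=0.5)
        assert entry.mpd == 0.0 and entry.mnd == 0.0
        assert entry.pde == 0.0 and entry.nde == 0.0

    def test_grown_ball_is_all_positive_one_voxel(self):
        small = ball_mask((24, 24, 24), (12, 12, 12), 7)
        grown = ball_mask((24, 24, 24), (12, 12, 12), 8)
        entry = deformation_map(small, grown, voxel_um=0.33)
        assert entry.nde == 0.0
        assert entry.positive_magnitudes.size > 0
        assert np.median(entry.positive_magnitudes) == pytest.approx(0.33, rel=0.5)

    def test_translation_mpd_mnd_match_shift(self):
        a = ball_mask((24, 24, 30), (12, 12, 12), 7)
        b = ball_mask((24, 24, 30), (12, 12, 15), 7)
        entry = deformation_map(a, b, voxel_um=0.33)
        assert entry.mpd == pytest.approx(3 * 0.33, rel=0.2)
        assert entry.mnd == pytest.approx(3 * 0.33, rel=0.2)

    def test_sign_partition(self):
        a = ball_mask((20, 20, 24), (10, 10, 10), 6)
        b = ball_mask((20, 20, 24), (10, 10, 13), 6)
        entry = deformation_map(a, b, voxel_um=1.0)
        pos = {tuple(p) for p in entry.positive_points}
        neg = {tuple(p) for p in entry.negative_points}
        assert not pos & neg

    def test_empty_cell_rejected(self):
        with pytest.raises(ValidationError):
            deformation_map(np.zeros((5, 5, 5), bool),
                            ball_mask((5, 5, 5), (2, 2, 2), 1), 1.0)


def make_tracks(centers, interval=1.0):
    centers = np.asarray(centers, dtype=float)
    K = centers.shape[1]
    return TrackTable(centers=centers, labels=list(range(1, K + 1)),
                      identity_map={k: "border" for k in range(1, K + 1)},
                      frame_interval=interval)


class TestMobilityAndRotation:
    def test_static_movie_all_parameters_zero(self):
        cell = ball_mask((16, 16, 16), (8, 8, 8), 5)
        cells = np.tile(np.where(cell, 1, 0), (4, 1, 1, 1))
        from ccmigrate.protrusion import deformation_fields
        fields = deformation_fields(cells, voxel_um=1.0)
        tracks = make_tracks(np.zeros((4, 1, 3)))
        table = mobility_params(tracks, tracks, fields)
        assert (table[["NS", "CS", "MPD", "MND", "PDE", "NDE"]].to_numpy()
                == 0).all()

    def test_injected_extension_raises_pde(self):
        base = ball_mask((20, 20, 30), (10, 10, 12), 6)
        extended = base | finger_mask((20, 20, 30), (10, 10, 17), 8, 2)
        still = deformation_map(base, base, 1.0)
        grown = deformation_map(base, extended, 1.0)
        assert grown.pde > still.pde

    def test_tangential_deformation_aligns_with_rotation(self, rotating_truth):
        from ccmigrate.protrusion import deformation_fields
        voxel = rotating_truth.cell_labels.voxel_size_zyx[0]
        fields = deformation_fields(rotating_truth.cell_labels.labels, voxel)
        assoc = rotation_association(rotating_truth.true_tracks, fields,
                                     rotating_truth.cluster_centers)
        assert assoc.mean_angle_deg < 30.0

    def test_radial_only_deformation_flags_frames(self):
        # concentric growth: positive vectors are radial, so every cross
        # product cancels and Q vanishes
        T = 4
        shape = (26, 26, 26)
        cells = np.stack([np.where(ball_mask(shape, (13, 13, 13), 6 + t), 1, 0)
                          for t in range(T)])
        from ccmigrate.protrusion import deformation_fields
        fields = deformation_fields(cells, voxel_um=1.0)
        centers = np.tile([[13.0, 13.0, 13.0]], (T, 1))[:, None, :]
        # nucleus off-center so r-hat is defined; displacements tiny but nonzero
        centers = centers + np.linspace(0, 0.3, T)[:, None, None]
        centers[:, 0, 0] += 3.0
        tracks = make_tracks(centers)
        assoc = rotation_association(tracks, fields,
                                     np.tile([13.0, 13.0, 13.0], (T, 1)))
        assert np.isnan(assoc.angles_deg).all()

    def test_pde_minus_nde_tracks_volume_change(self):
        rng = np.random.default_rng(0)
        shape = (26, 26, 26)
        radii = [6, 7, 6, 8, 5, 7, 6]
        cells = np.stack([np.where(ball_mask(shape, (13, 13, 13), r), 1, 0)
                          for r in radii])
        from ccmigrate.protrusion import deformation_fields
        fields = deformation_fields(cells, voxel_um=1.0)
        signal = [f[0].pde - f[0].nde for f in fields]
        dvol = np.diff([(c > 0).sum() for c in cells])
        from scipy.stats import spearmanr
        rho = spearmanr(signal, dvol).statistic
        assert rho > 0.8
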