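"""Order parameters, mode classification, polar axis and neighbour
exchange detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ccmigrate.coordination import (
    ModeClassifier,
    angular_momentum,
    classify_mode,
    default_mode_classifier,
    detect_exchanges,
    exchange_metric,
    fit_mode_classifier,
    group_polarization,
    moving_average,
    polar_axis_series,
)


class TestGroupPolarization:
    def test_identical_directions_give_one(self):
        d = np.tile([0.0, 0.0, 1.0], (7, 1))
        assert group_polarization(d) == pytest.approx(1.0)

    def test_antiparallel_pair_cancels(self):
        d = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        assert group_polarization(d) == pytest.approx(0.0)

    def test_hand_computed_four_vector_case(self):
        # (+x, -x, +y, +y) -> |(0, 2, 0)| / 4 = 0.5
        d = np.array([[0, 0, 1.0], [0, 0, -1.0], [0, 1.0, 0], [0, 1.0, 0]])
        assert group_polarization(d) == pytest.approx(0.5)

    def test_all_invalid_flags_undefined(self):
        assert np.isnan(group_polarization(np.full((3, 3), np.nan)))


class TestAngularMomentum:
    def test_equatorial_rotation_gives_one(self):
        phis = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        centers = np.stack([np.zeros(8), np.sin(phis), np.cos(phis)], axis=1)
        tangents = np.stack([np.zeros(8), np.cos(phis), -np.sin(phis)], axis=1)
        assert angular_momentum(tangents, centers, np.zeros(3)) \
            == pytest.approx(1.0)

    def test_radial_directions_give_zero(self):
        phis = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        centers = np.stack([np.zeros(6), np.sin(phis), np.cos(phis)], axis=1)
        assert angular_momentum(centers, centers, np.zeros(3)) \
            == pytest.approx(0.0)

    def test_matches_manual_cross_product_arithmetic(self):
        centers = np.array([[0, 1.0, 0], [0, -1.0, 0], [0, 0, 1.0], [0, 0, -1.0]])
        dirs = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]])
        manual = np.cross(centers, dirs).sum(axis=0)
        expected = np.linalg.norm(manual) / 4
        assert angular_momentum(dirs, centers, np.zeros(3)) \
            == pytest.approx(expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(arrays(float, (6, 3), elements=st.floats(-1, 1)),
           arrays(float, (6, 3), elements=st.floats(-10, 10)))
    def test_normalization_bounds(self, raw_dirs, centers):
        norms = np.linalg.norm(raw_dirs, axis=1, keepdims=True)
        dirs = np.where(norms > 1e-6, raw_dirs / np.where(norms == 0, 1, norms),
                        np.nan)
        P = group_polarization(dirs)
        M = angular_momentum(dirs, centers, centers.mean(axis=0))
        for value in (P, M):
            assert np.isnan(value) or 0.0 <= value <= 1.0 + 1e-12


class TestModeClassifier:
    def mirrored_samples(self):
        rng = np.random.default_rng(0)
        run = rng.normal([0.8, 0.2], 0.05, size=(50, 2))
        rot = run[:, ::-1]
        return ([(p, m, "running") for p, m in run]
                + [(p, m, "rotating") for p, m in rot])

    def test_mirrored_classes_have_diagonal_boundary(self):
        clf = fit_mode_classifier(self.mirrored_samples())
        for v in np.linspace(0.1, 0.9, 9):
            joint = clf.log_joint(v, v)
            assert joint["running"] == pytest.approx(joint["rotating"], abs=1e-8)

    def test_tight_clusters_classify_their_own_points(self):
        samples = self.mirrored_samples()
        clf = fit_mode_classifier(samples)
        for p, m, mode in samples:
            assert classify_mode(p, m, clf)[0] == mode

    def test_boundary_tie_is_running_with_half_posterior(self):
        clf = fit_mode_classifier(self.mirrored_samples())
        mode, post = classify_mode(0.5, 0.5, clf)
        assert mode == "running" and post == pytest.approx(0.5, abs=1e-6)

    def test_default_classifier_separates_obvious_cases(self):
        clf = default_mode_classifier(seed=0)
        assert classify_mode(0.95, 0.05, clf)[0] == "running"
        assert classify_mode(0.05, 0.95, clf)[0] == "rotating"

    def test_default_classifier_held_out_accuracy(self):
        clf = default_mode_classifier(seed=0)
        rng = np.random.default_rng(123)
        correct = 0
        total = 200
        for i in range(total):
            truth = "running" if i % 2 == 0 else "rotating"
            if truth == "running":
                heading = rng.normal(size=3)
                heading /= np.linalg.norm(heading)
                dirs = heading + 0.35 * rng.normal(size=(8, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                centers = rng.normal(size=(8, 3))
                P = group_polarization(dirs)
                M = angular_momentum(dirs, centers, centers.mean(axis=0))
            else:
                phis = rng.uniform(0, 2 * np.pi, 8)
                centers = np.stack([np.zeros(8), np.sin(phis), np.cos(phis)], axis=1)
                dirs = np.stack([np.zeros(8), np.cos(phis), -np.sin(phis)], axis=1)
                dirs = dirs + 0.35 * rng.normal(size=(8, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                P = group_polarization(dirs)
                M = angular_momentum(dirs, centers, np.zeros(3))
            if classify_mode(P, M, clf)[0] == truth:
                correct += 1
        assert correct / total >= 0.90


class TestPolarAxis:
    def test_static_axis_zero_step_angles(self):
        pc = np.tile(np.array([[0, 2.0, 0], [0, -2.0, 0.0]]), (5, 1, 1))
        _, angles, smooth = polar_axis_series(pc)
        np.testing.assert_allclose(angles, 0.0, atol=1e-9)
        np.testing.assert_allclose(smooth, 0.0, atol=1e-9)

    def test_precession_recovers_step_angle(self):
        T, step = 8, np.radians(10.0)
        pc = np.zeros((T, 2, 3))
        for t in range(T):
            a = t * step
            axis = np.array([0.0, np.sin(a), np.cos(a)])
            pc[t, 0] = 2.0 * axis
            pc[t, 1] = -2.0 * axis
        _, angles, _ = polar_axis_series(pc)
        np.testing.assert_allclose(angles, 10.0, atol=1e-9)

    def test_sign_flip_is_invisible(self):
        rng = np.random.default_rng(0)
        pc = rng.normal(size=(6, 2, 3))
        _, a1, _ = polar_axis_series(pc)
        flipped = pc[:, ::-1, :]
        _, a2, _ = polar_axis_series(flipped)
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_moving_average_shrinks_at_ends(self):
        x = np.arange(7, dtype=float)
        out = moving_average(x, 5)
        assert out[0] == pytest.approx(np.mean(x[:3]))
        assert out[3] == pytest.approx(np.mean(x[1:6]))


class TestExchangeMetric:
    def ring(self, T=12, K=6, radius=9.0):
        phis = 2 * np.pi * np.arange(K) / K
        rel = np.stack([np.zeros(K), radius * np.sin(phis),
                        radius * np.cos(phis)], axis=1)
        return np.tile(rel, (T, 1, 1))

    def test_static_cluster_zero_everywhere(self):
        space = exchange_metric(self.ring(), max_step=5)
        np.testing.assert_allclose(np.nan_to_num(space.g), 0.0, atol=1e-9)
        assert detect_exchanges(space, tau_um=1.0) == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        base = self.ring(T=8)
        moved = np.empty_like(base)
        for t in range(base.shape[0]):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            shift = rng.uniform(-30, 30, 3)
            moved[t] = base[t] @ R.T + shift
        space = exchange_metric(moved, max_step=4)
        np.testing.assert_allclose(np.nan_to_num(space.g), 0.0, atol=1e-8)

    def test_swap_magnitude_matches_distance_matrix_oracle(self):
        from scipy.spatial.distance import cdist

        from ccmigrate.synthetic import ExchangeEvent, inject_exchange

        pos = self.ring(T=14)
        out = inject_exchange(pos, ExchangeEvent(1, 4, 5, 3))
        space = exchange_metric(out, max_step=6)
        # oracle: recompute one entry directly from the distance matrices
        t, s = 4, 6
        oracle = np.abs(cdist(out[t + s], out[t + s]) - cdist(out[t], out[t])).max()
        assert space.g[t, s] == pytest.approx(oracle)
        assert np.nanmax(space.g) > 0

    def test_g_at_step_zero_is_zero(self):
        space = exchange_metric(self.ring(), max_step=3)
        np.testing.assert_allclose(space.g[:, 0], 0.0)
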