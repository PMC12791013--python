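"""Imputation metrics against hand values and brute-force oracles."""

import numpy as np
import pytest

from skelimpute import metrics as M
from skelimpute.errors import EmptyInputError, UndefinedMetricError
from skelimpute.io import Recording, Sample


def brute_force_metrics(pred, gt, mask, th, max_dist):
    """Independent scalar-loop oracle for rmse / mpjpe / pck."""
    sq, dists = [], []
    T, K, D = pred.shape
    for t in range(T):
        for k in range(K):
            if not mask[t, k]:
                continue
            s = sum((pred[t, k, d] - gt[t, k, d]) ** 2 for d in range(D))
            sq.append(s)
            dists.append(np.sqrt(s))
    rmse = np.sqrt(np.mean(sq))
    mpjpe = np.mean(dists)
    pck = np.mean([d < th * max_dist for d in dists])
    return rmse, mpjpe, pck


class TestPointMetrics:
    def test_perfect_prediction(self, rng):
        gt = rng.normal(size=(5, 3, 3))
        m = np.ones((5, 3), bool)
        assert M.rmse(gt, gt, m) == 0.0
        assert M.mpjpe(gt, gt, m) == 0.0
        assert M.pck(gt, gt, m, 0.01, 1.0) == 1.0

    def test_three_four_five_triangle(self):
        gt = np.zeros((1, 2, 3))
        pred = np.zeros((1, 2, 3))
        m = np.zeros((1, 2), bool)
        m[0, 0] = True
        pred[0, 0] = [3.0, 4.0, 0.0]
        assert M.rmse(pred, gt, m) == pytest.approx(5.0)
        assert M.mpjpe(pred, gt, m) == pytest.approx(5.0)

    def test_two_point_hand_formula(self):
        gt = np.zeros((2, 1, 3))
        pred = np.zeros((2, 1, 3))
        m = np.ones((2, 1), bool)
        pred[1, 0] = [3.0, 4.0, 0.0]
        assert M.rmse(pred, gt, m) == pytest.approx(np.sqrt(25 / 2))
        assert M.mpjpe(pred, gt, m) == pytest.approx(2.5)

    def test_pck_counts_fraction_below_threshold(self):
        gt = np.zeros((2, 1, 2))
        pred = np.zeros((2, 1, 2))
        m = np.ones((2, 1), bool)
        pred[0, 0] = [0.5, 0.0]
        pred[1, 0] = [2.0, 0.0]
        assert M.pck(pred, gt, m, th=1.0, max_dist=1.0) == 0.5
        assert M.pck(pred, gt, m, th=0.1, max_dist=1.0) == 0.0

    def test_agree_with_brute_force_oracle(self, rng):
        for _ in range(50):
            pred = rng.normal(size=(6, 4, 3))
            gt = rng.normal(size=(6, 4, 3))
            m = rng.random((6, 4)) < 0.4
            if not m.any():
                m[0, 0] = True
            r, p, c = brute_force_metrics(pred, gt, m, 0.5, 2.0)
            assert M.rmse(pred, gt, m) == pytest.approx(r, abs=1e-9)
            assert M.mpjpe(pred, gt, m) == pytest.approx(p, abs=1e-9)
            assert M.pck(pred, gt, m, 0.5, 2.0) == pytest.approx(c, abs=1e-9)

    def test_mpjpe_never_exceeds_rmse(self, rng):
        for _ in range(20):
            pred = rng.normal(size=(5, 3, 2))
            gt = rng.normal(size=(5, 3, 2))
            m = rng.random((5, 3)) < 0.5
            if not m.any():
                m[0, 0] = True
            assert M.mpjpe(pred, gt, m) <= M.rmse(pred, gt, m) + 1e-12

    def test_pck_monotone_in_threshold(self, rng):
        pred = rng.normal(size=(8, 4, 3))
        gt = rng.normal(size=(8, 4, 3))
        m = np.ones((8, 4), bool)
        vals = [M.pck(pred, gt, m, th, 1.0) for th in np.linspace(0.01, 3, 20)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_invariant_to_error_on_unmasked_cells(self, rng):
        pred = rng.normal(size=(6, 3, 3))
        gt = rng.normal(size=(6, 3, 3))
        m = rng.random((6, 3)) < 0.3
        m[0, 0] = True
        pred2 = pred.copy()
        pred2[~m] += 100.0
        for fn in (M.rmse, M.mpjpe):
            assert fn(pred, gt, m) == fn(pred2, gt, m)

    def test_empty_mask_is_undefined(self, rng):
        gt = rng.normal(size=(3, 2, 2))
        with pytest.raises(UndefinedMetricError):
            M.rmse(gt, gt, np.zeros((3, 2), bool))


class TestMaxInterKeypointDistance:
    def test_unit_square_diagonal(self):
        coords = np.array([[[0, 0], [1, 0], [0, 1], [1, 1]]], dtype=float)
        rec = Recording("sq", 60.0, list("abcd"), coords)
        assert M.max_interkeypoint_distance([rec]) == pytest.approx(np.sqrt(2))

    def test_missing_keypoints_excluded(self):
        coords = np.array([[[0, 0], [1, 0], [0, 1], [100, 100]]], dtype=float)
        missing = np.array([[False, False, False, True]])
        coords[missing] = np.nan
        rec = Recording("sq", 60.0, list("abcd"), coords, missing)
        assert M.max_interkeypoint_distance([rec]) == pytest.approx(np.sqrt(2))

    def test_agrees_with_pairwise_loop(self, rng):
        coords = rng.normal(size=(20, 5, 3))
        rec = Recording("r", 60.0, list("abcde"), coords)
        best = 0.0
        for t in range(20):
            for i in range(5):
                for j in range(i + 1, 5):
                    best = max(best, np.linalg.norm(coords[t, i] - coords[t, j]))
        assert M.max_interkeypoint_distance([rec]) == pytest.approx(best, abs=1e-9)


class TestMotionDescriptors:
    def test_movement_zero_for_static_sample(self):
        s = Sample("r", 0, np.ones((10, 3, 2)), np.zeros((10, 3), bool))
        assert M.movement(s) == 0.0

    def test_movement_equals_constant_increment(self):
        coords = np.cumsum(np.full((10, 2, 3), 0.25), axis=0)
        s = Sample("r", 0, coords, np.zeros((10, 2), bool))
        assert M.movement(s) == pytest.approx(0.25)

    def test_movement_matches_brute_force(self, rng):
        coords = rng.normal(size=(12, 3, 3))
        s = Sample("r", 0, coords, np.zeros((12, 3), bool))
        acc = [abs(coords[t, k, d] - coords[t - 1, k, d])
               for t in range(1, 12) for k in range(3) for d in range(3)]
        assert M.movement(s) == pytest.approx(np.mean(acc), abs=1e-12)

    def test_movement_requires_complete_sample(self, rng):
        s = Sample("r", 0, rng.normal(size=(10, 2, 2)),
                   np.zeros((10, 2), bool))
        s.missing[0, 0] = True
        with pytest.raises(EmptyInputError):
            M.movement(s)

    def test_periodicity_picks_the_sinusoidal_coordinate(self):
        L = 60
        t = np.arange(L)
        coords = np.zeros((L, 2, 2))
        coords[:, 0, 0] = 3.0 * np.sin(2 * np.pi * 5 * t / L)
        coords[:, 1, 1] = 7.0  # constant offset must not dominate
        s = Sample("r", 0, coords, np.zeros((L, 2), bool))
        assert M.periodicity(s) == pytest.approx(3.0, rel=1e-6)

    def test_periodicity_zero_for_constant_sample(self):
        s = Sample("r", 0, np.full((20, 2, 2), 4.2), np.zeros((20, 2), bool))
        assert M.periodicity(s) == pytest.approx(0.0, abs=1e-12)

    def test_periodicity_scales_linearly_with_amplitude(self, rng):
        coords = rng.normal(size=(30, 2, 3))
        s1 = Sample("r", 0, coords, np.zeros((30, 2), bool))
        s2 = Sample("r", 0, 2 * coords, np.zeros((30, 2), bool))
        assert M.periodicity(s2) == pytest.approx(2 * M.periodicity(s1))
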