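import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from lsatrace.segmentation import (IntensityInterval, dice, extract_patch, fp_fn_rates,
                                   fp_fn_rates_conventional, hausdorff,
                                   prescreen_candidates)
from lsatrace.volume import Volume


def _std_volume(data):
    return Volume(np.asarray(data, dtype=float), (0.1,) * 3, intensity_scale="standardized")


class TestPrescreen:
    def test_all_bright_goes_to_large_vessel(self):
        cands, large, bg = prescreen_candidates(_std_volume(np.full((5, 5, 5), 200.0)))
        assert len(cands) == 0 and large.all() and not bg.any()

    def test_all_dark_goes_to_background(self):
        cands, large, bg = prescreen_candidates(_std_volume(np.full((5, 5, 5), 50.0)))
        assert len(cands) == 0 and bg.all() and not large.any()

    def test_single_mid_intensity_voxel_is_the_only_candidate(self):
        data = np.full((5, 5, 5), 50.0)
        data[2, 2, 2] = 100.0
        cands, _large, _bg = prescreen_candidates(_std_volume(data))
        assert len(cands) == 1 and tuple(cands[0]) == (2, 2, 2)

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        data = rng.uniform(0, 255, (10, 10, 10))
        v = _std_volume(data)
        cands, large, bg = prescreen_candidates(v)
        cand_mask = np.zeros(v.shape, dtype=np.uint8)
        cand_mask[cands[:, 0], cands[:, 1], cands[:, 2]] = 1
        total = cand_mask.astype(int) + large.astype(int) + bg.astype(int)
        assert (total == 1).all()

    def test_boundary_values_are_not_candidates(self):
        data = np.full((3, 3, 3), 80.0)
        data[0, 0, 0] = 120.0
        cands, large, bg = prescreen_candidates(_std_volume(data))
        assert len(cands) == 0 and large.sum() == 1 and bg.sum() == 26

    def test_requires_standardized_volume(self):
        with pytest.raises(ValueError, match="standardized"):
            prescreen_candidates(Volume(np.zeros((3, 3, 3)), (0.1,) * 3))

    def test_interval_invariant(self):
        with pytest.raises(ValueError):
            IntensityInterval(t_bg=120, t_v=80)


class TestExtractPatch:
    def test_requested_cube_size(self, rng):
        v = _std_volume(rng.uniform(0, 255, (30, 30, 30)))
        assert extract_patch(v, (15, 15, 15), 25, 0, 255).shape == (25, 25, 25)

    def test_constant_at_norm_min_gives_zeros(self):
        v = _std_volume(np.full((9, 9, 9), 10.0))
        assert np.all(extract_patch(v, (4, 4, 4), 5, 10.0, 20.0) == 0.0)

    def test_corner_center_uses_edge_replication(self):
        v = _std_volume(np.arange(27.0).reshape(3, 3, 3))
        p = extract_patch(v, (0, 0, 0), 5, 0, 26)
        assert p.shape == (5, 5, 5)
        assert np.isclose(p[2, 2, 2], 0.0)       # true corner value 0
        assert np.isclose(p[0, 0, 0], 0.0)       # replicated edge

    def test_center_outside_grid_raises(self):
        v = _std_volume(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="outside"):
            extract_patch(v, (9, 0, 0), 3, 0, 1)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), np.uint8)
        m[1:3, 1:3, 1:3] = 1
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dice(a, b) == 0.0

    def test_worked_three_voxel_case(self):
        """pred {a,b,c} vs gt {a,b,d}: TP=2, FP=1, FN=1 -> 4/6."""
        pred = np.zeros((3, 3, 3), np.uint8)
        gt = np.zeros((3, 3, 3), np.uint8)
        pred[0, 0, 0] = pred[0, 0, 1] = pred[0, 0, 2] = 1
        gt[0, 0, 0] = gt[0, 0, 1] = gt[0, 1, 0] = 1
        assert dice(pred, gt) == pytest.approx(4 / 6)

    def test_empty_vs_empty_is_one(self):
        z = np.zeros((3, 3, 3), np.uint8)
        assert dice(z, z) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))


class TestHausdorff:
    def test_identical_sets_zero(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[2, 2, :] = 1
        assert hausdorff(m, m, (0.1,) * 3) == 0.0

    def test_asymmetric_two_point_case(self):
        """P = {p}, G = {p, p + 3 mm z}: the directed asymmetry forces HD = 3 mm."""
        P = np.zeros((2, 2, 40), np.uint8)
        G = np.zeros((2, 2, 40), np.uint8)
        P[0, 0, 0] = 1
        G[0, 0, 0] = 1
        G[0, 0, 30] = 1  # 30 voxels x 0.1 mm = 3 mm
        assert hausdorff(P, G, (0.1, 0.1, 0.1)) == pytest.approx(3.0)

    def test_empty_mask_raises(self):
        m = np.zeros((3, 3, 3), np.uint8)
        n = m.copy()
        n[0, 0, 0] = 1
        with pytest.raises(ValueError, match="empty"):
            hausdorff(m, n)


def _brute_dice(pred, gt):
    tp = np.sum(pred & gt)
    fp = np.sum(pred & ~gt)
    fn = np.sum(~pred & gt)
    if tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


def _brute_hausdorff(pred, gt, spacing):
    P = np.argwhere(pred) * np.asarray(spacing)
    G = np.argwhere(gt) * np.asarray(spacing)
    D = cdist(P, G)
    return max(D.min(axis=1).max(), D.min(axis=0).max())


class TestMetricOracles:
    def test_agree_with_brute_force_on_random_masks(self):
        """100 random <=100-voxel mask pairs, exact agreement with O(|P||G|) oracles."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = (8, 8, 8)
            a = np.zeros(shape, bool)
            b = np.zeros(shape, bool)
            na, nb = rng.integers(1, 101, 2)
            a[tuple(rng.integers(0, 8, (3, na)))] = True
            b[tuple(rng.integers(0, 8, (3, nb)))] = True
            sp = rng.uniform(0.05, 0.4, 3)
            assert dice(a, b) == pytest.approx(_brute_dice(a, b), abs=0)
            assert hausdorff(a, b, sp) == pytest.approx(_brute_hausdorff(a, b, sp), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[tuple(rng.integers(1, 7, (3, 20)))] = True
        b[tuple(rng.integers(1, 7, (3, 20)))] = True
        assert dice(a, b) == dice(b, a)
        assert hausdorff(a, b) == hausdorff(b, a)
        sh = (2, 1, 3)
        at = np.roll(a, sh, axis=(0, 1, 2))
        bt = np.roll(b, sh, axis=(0, 1, 2))
        assert dice(at, bt) == pytest.approx(dice(a, b))
        assert hausdorff(at, bt) == pytest.approx(hausdorff(a, b))


class TestRates:
    def test_perfect_prediction(self):
        gt = np.zeros((5, 5, 5), np.uint8)
        gt[2, 2, :] = 1
        assert fp_fn_rates(gt, gt) == (0.0, 0.0)

    def test_printed_fp_definition_uses_vessel_denominator(self):
        """10 vessel voxels in gt, 2 spurious predictions -> FP rate 0.2."""
        gt = np.zeros((5, 5, 5), np.uint8)
        gt[0, 0, :5] = 1
        gt[0, 1, :5] = 1
        pred = gt.copy()
        pred[4, 4, 0] = pred[4, 4, 1] = 1
        fp, fn = fp_fn_rates(pred, gt)
        assert fp == pytest.approx(2 / 10)
        assert fn == 0.0

    def test_printed_fn_definition_uses_background_denominator(self):
        gt = np.zeros((5, 5, 4), np.uint8)
        gt[0, 0, :4] = 1
        gt[0, 1, :4] = 1
        gt[0, 2, :4] = 1
        gt[0, 3, :4] = 1
        gt[1, 0, :4] = 1                      # 20 vessel, 80 background
        pred = gt.copy()
        pred[0, 0, :4] = 0                    # miss 4 vessel voxels
        fp, fn = fp_fn_rates(pred, gt)
        assert fn == pytest.approx(4 / 80)
        assert fp == 0.0

    def test_conventional_rates_swap_denominators(self):
        gt = np.zeros((4, 4, 4), np.uint8)
        gt[0, 0, :2] = 1
        pred = np.zeros_like(gt)
        pred[0, 0, 0] = 1
        pred[3, 3, 3] = 1
        fp_p, fn_p = fp_fn_rates(pred, gt)
        fp_c, fn_c = fp_fn_rates_conventional(pred, gt)
        assert fp_p == pytest.approx(1 / 2)
        assert fn_p == pytest.approx(1 / 62)
        assert fp_c == pytest.approx(1 / 62)
        assert fn_c == pytest.approx(1 / 2)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            fp_fn_rates(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))
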