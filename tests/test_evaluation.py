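"""Closed forms and invariants of the nine-index evaluation suite."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cascadereg.evaluation import (evaluate_case, overlap_metrics, rmse_psnr,
                                   ssim, surface_distances)
from cascadereg.volume_io import LabelVolume, Volume

GRID = (8, 8, 8)


def _vol(arr):
    return Volume(np.asarray(arr, dtype=np.float32))


def _lab(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(arr, dtype=np.int32), spacing)


class TestIntensityMetrics:
    def test_identical_volumes(self, rng):
        a = _vol(rng.random(GRID))
        r, p = rmse_psnr(a, a)
        assert r == 0.0 and p == np.inf
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_constant_offset_closed_form(self, rng):
        a = rng.random(GRID).astype(np.float32) * 0.5
        r, p = rmse_psnr(_vol(a), _vol(a + 0.1))
        assert r == pytest.approx(0.1, rel=1e-5)
        assert p == pytest.approx(20.0, rel=1e-4)  # 10 log10(1 / 0.01)

    def test_zero_vs_one(self):
        r, p = rmse_psnr(_vol(np.zeros(GRID)), _vol(np.ones(GRID)))
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_ssim_penalizes_luminance_shift(self, rng):
        a = rng.random(GRID).astype(np.float32) * 0.4
        assert ssim(_vol(a), _vol(a + 0.5)) < 1.0

    def test_ssim_two_voxel_hand_arithmetic(self):
        a = np.array([0.0, 1.0]).reshape(2, 1, 1)
        b = np.array([0.5, 1.0]).reshape(2, 1, 1)
        c1, c2 = 0.01 ** 2, 0.03 ** 2
        mu_a, mu_b = 0.5, 0.75
        var_a, var_b, cov = 0.25, 0.0625, 0.125
        expected = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / \
            ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))
        assert ssim(_vol(a), _vol(b)) == pytest.approx(expected, rel=1e-12)


class TestOverlapMetrics:
    def test_identical_masks_perfect(self, rng):
        lab = _lab(rng.integers(0, 3, GRID))
        dice, iou, ss, sc = overlap_metrics(lab, lab)
        for d in (dice, iou, ss, sc):
            assert all(v == 1.0 for v in d.values())

    def test_disjoint_masks(self):
        x = np.zeros(GRID, dtype=np.int32)
        y = np.zeros(GRID, dtype=np.int32)
        x[:2] = 1
        y[4:6] = 1
        dice, iou, ss, _ = overlap_metrics(_lab(x), _lab(y))
        assert dice[1] == 0.0 and iou[1] == 0.0 and ss[1] == 0.0

    def test_hand_counted_contingency(self):
        # |X| = 6, |Y| = 4, overlap 3 on a 4^3 grid
        x = np.zeros((4, 4, 4), dtype=np.int32)
        y = np.zeros((4, 4, 4), dtype=np.int32)
        x.ravel()[:6] = 1
        y.ravel()[3:7] = 1
        dice, iou, ss, sc = overlap_metrics(_lab(x), _lab(y))
        assert dice[1] == pytest.approx(2 * 3 / (6 + 4))
        assert iou[1] == pytest.approx(3 / 7)
        assert ss[1] == pytest.approx(3 / 6)
        tn, fp = 64 - 7, 1
        assert sc[1] == pytest.approx(tn / (tn + fp))

    def test_sc_as_printed_variant(self):
        x = np.zeros((4, 4, 4), dtype=np.int32)
        y = np.zeros((4, 4, 4), dtype=np.int32)
        x.ravel()[:6] = 1
        y.ravel()[3:7] = 1
        _, _, _, sc = overlap_metrics(_lab(x), _lab(y), sc_as_printed=True)
        assert sc[1] == pytest.approx(3 / (57 + 1))

    def test_dice_iou_identity_on_random_masks(self, rng):
        for _ in range(10):
            a = _lab(rng.integers(0, 4, GRID))
            b = _lab(rng.integers(0, 4, GRID))
            dice, iou, _, _ = overlap_metrics(a, b)
            for lab in dice:
                assert dice[lab] == pytest.approx(
                    2 * iou[lab] / (1 + iou[lab]), abs=1e-12)

    def test_absent_label_warns_and_is_skipped(self):
        x = np.zeros(GRID, dtype=np.int32)
        x[0, 0, 0] = 2
        y = np.zeros(GRID, dtype=np.int32)
        y[0, 0, 0] = 2
        with pytest.warns(UserWarning, match="label 3"):
            dice, _, _, _ = overlap_metrics(_lab(x), _lab(y), labels=[2, 3])
        assert set(dice) == {2}


def brute_force_directed_max(src_pts, dst_pts, spacing):
    d = cdist(src_pts * spacing, dst_pts * spacing)
    return d.min(axis=1).max()


class TestSurfaceDistances:
    def test_identical_masks_zero(self, rng):
        lab = _lab((rng.random(GRID) > 0.7).astype(np.int32))
        hd, cmd = surface_distances(lab, lab)
        assert hd[1] == 0.0 and cmd[1] == 0.0

    def test_two_single_voxels_three_apart(self):
        x = np.zeros(GRID, dtype=np.int32)
        y = np.zeros(GRID, dtype=np.int32)
        x[2, 2, 2] = 1
        y[2, 2, 5] = 1
        hd, cmd = surface_distances(_lab(x), _lab(y))
        assert hd[1] == pytest.approx(3.0)
        assert cmd[1] == pytest.approx(3.0)

    def test_dilated_cube_contour_distance_one(self):
        x = np.zeros((12, 12, 12), dtype=np.int32)
        x[4:8, 4:8, 4:8] = 1
        from scipy import ndimage
        y = ndimage.binary_dilation(
            x.astype(bool),
            structure=ndimage.generate_binary_structure(3, 1)).astype(np.int32)
        hd, cmd = surface_distances(_lab(x), _lab(y))
        assert cmd[1] == pytest.approx(1.0)

    def test_spacing_scales_distances(self):
        x = np.zeros(GRID, dtype=np.int32)
        y = np.zeros(GRID, dtype=np.int32)
        x[2, 2, 2] = 1
        y[2, 2, 5] = 1
        hd, _ = surface_distances(_lab(x, spacing=(1, 1, 2)),
                                  _lab(y, spacing=(1, 1, 2)))
        assert hd[1] == pytest.approx(6.0)

    def test_empty_mask_reported_missing(self):
        x = np.zeros(GRID, dtype=np.int32)
        x[0, 0, 0] = 1
        hd, cmd = surface_distances(_lab(x), _lab(np.zeros(GRID)))
        assert np.isnan(hd[1]) and np.isnan(cmd[1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        shape = (10, 10, 10)
        x = (rng.random(shape) > 0.8).astype(np.int32)
        y = (rng.random(shape) > 0.8).astype(np.int32)
        spacing = np.array([1.0, 1.5, 2.0])
        hd, _ = surface_distances(_lab(x, spacing=tuple(spacing)),
                                  _lab(y, spacing=tuple(spacing)))
        xp = np.argwhere(x > 0)
        yp = np.argwhere(y > 0)
        expected = max(brute_force_directed_max(xp, yp, spacing),
                       brute_force_directed_max(yp, xp, spacing))
        assert hd[1] == pytest.approx(expected, rel=1e-9)


class TestEvaluateCase:
    def test_perfect_registration(self, small_case):
        rep = evaluate_case(small_case.fixed, small_case.fixed,
                            small_case.fixed_labels, small_case.fixed_labels)
        d = rep.as_dict()
        assert d["RMSE"] == 0.0 and d["DICE"] == 1.0 and d["HD (mm)"] == 0.0
        assert d["PSNR"] == np.inf

    def test_unregistered_pair_scores_below_perfect(self, small_case):
        rep = evaluate_case(small_case.fixed, small_case.moving,
                            small_case.fixed_labels, small_case.moving_labels)
        d = rep.as_dict()
        assert 0 < d["DICE"] < 1
        assert d["RMSE"] > 0

    def test_dice_iou_identity_per_label(self, small_case):
        rep = evaluate_case(small_case.fixed, small_case.moving,
                            small_case.fixed_labels, small_case.moving_labels)
        for lab in rep.label_set:
            assert rep.dice[lab] == pytest.approx(
                2 * rep.iou[lab] / (1 + rep.iou[lab]), abs=1e-12)

    def test_translation_of_both_grids_leaves_metrics_unchanged(self, rng):
        # content confined to the interior so np.roll is a true translation
        vol = np.zeros(GRID, dtype=np.float32)
        lab = np.zeros(GRID, dtype=np.int32)
        vol2 = np.zeros(GRID, dtype=np.float32)
        lab2 = np.zeros(GRID, dtype=np.int32)
        core = (slice(2, 5),) * 3
        vol[core] = rng.random((3, 3, 3))
        lab[core] = rng.integers(0, 3, (3, 3, 3))
        vol2[core] = rng.random((3, 3, 3))
        lab2[core] = rng.integers(0, 3, (3, 3, 3))
        r1 = evaluate_case(_vol(vol), _vol(vol2), _lab(lab), _lab(lab2))
        shift = lambda a: np.roll(a, (1, 2, 1), axis=(0, 1, 2))
        r2 = evaluate_case(_vol(shift(vol)), _vol(shift(vol2)),
                           _lab(shift(lab)), _lab(shift(lab2)))
        assert r1.as_dict() == pytest.approx(r2.as_dict(), rel=1e-6)
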