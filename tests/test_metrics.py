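"""Scoring layer: Dice family against set-arithmetic brute force, texture
moments, image quality, detection reports, group statistics,
bias-variance identity."""

import numpy as np
import pandas as pd
import pytest

from strokeseg.core import ImageVolume, SegmentationMask, ValidationError
from strokeseg.metrics_losses import (EvalReport, bias_variance, chi_square_2x2,
                                      compare_groups, detection_report,
                                      dice_scores, image_quality,
                                      render_efficacy_table,
                                      render_quality_table, soft_dice_loss,
                                      soft_new_dice_loss, texture_features)


def set_oracle(e, f):
    """Independent Dice/New-Dice via python-set arithmetic on coordinates."""
    E = {tuple(i) for i in np.argwhere(e)}
    F = {tuple(i) for i in np.argwhere(f)}
    inter = len(E & F)
    dice = 2 * inter / (len(E) + len(F))
    new = 2 * (inter - len(F - E) - len(E - F)) / (len(E) + len(F))
    return dice, new


class TestDiceFamily:
    def test_perfect_agreement(self):
        m = np.zeros((4, 4), dtype=int)
        m[1:3, 1:3] = 1
        s = dice_scores(m, m)
        assert (s.dice, s.dice_distance, s.new_dice) == (1.0, 0.0, 1.0)

    def test_disjoint_masks(self):
        e = np.zeros((4, 4), dtype=int)
        f = np.zeros((4, 4), dtype=int)
        e[0, 0] = 1
        f[3, 3] = 1
        s = dice_scores(e, f)
        assert (s.dice, s.new_dice) == (0.0, -2.0)

    def test_hand_worked_overlap_case(self):
        """|E| = 6, |F| = 4, overlap 3: dice 0.6, new_dice -0.2."""
        e = np.zeros((4, 4), dtype=int)
        f = np.zeros((4, 4), dtype=int)
        e.flat[:6] = 1
        f.flat[3:7] = 1  # overlap cells 3,4,5
        s = dice_scores(e, f)
        assert s.dice == pytest.approx(0.6)
        assert s.new_dice == pytest.approx(-0.2)
        assert (s.tp, s.fp, s.fn) == (3, 3, 1)

    def test_both_empty_is_invalid_case(self):
        z = np.zeros((4, 4), dtype=int)
        with pytest.raises(ValidationError, match="0/0"):
            dice_scores(z, z)

    def test_agrees_with_set_arithmetic_on_random_masks(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            e = rng.random((6, 6)) < 0.4
            f = rng.random((6, 6)) < 0.4
            if not (e.any() or f.any()):
                continue
            s = dice_scores(e.astype(int), f.astype(int))
            d, n = set_oracle(e, f)
            assert s.dice == pytest.approx(d)
            assert s.new_dice == pytest.approx(n)
            # structural relations
            assert s.new_dice <= s.dice + 1e-12
            assert (s.new_dice == s.dice) == (s.fp == 0 and s.fn == 0)

    def test_symmetry_in_prediction_and_truth(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            e = (rng.random((5, 5)) < 0.5).astype(int)
            f = (rng.random((5, 5)) < 0.5).astype(int)
            if not (e.any() or f.any()):
                continue
            a, b = dice_scores(e, f), dice_scores(f, e)
            assert a.dice == b.dice and a.new_dice == b.new_dice


class TestSoftLosses:
    def test_exact_prediction_gives_zero_loss(self):
        f = np.zeros((4, 4))
        f[1:3, 1:3] = 1.0
        assert soft_dice_loss(f, f.astype(int)) == pytest.approx(0.0)
        assert soft_new_dice_loss(f, f.astype(int)) == pytest.approx(0.0)

    def test_hard_masks_agree_with_set_arithmetic(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            e = (rng.random((5, 5)) < 0.5).astype(float)
            f = (rng.random((5, 5)) < 0.5).astype(int)
            if not (e.any() or f.any()):
                continue
            s = dice_scores(e.astype(int), f)
            assert soft_dice_loss(e, f) == pytest.approx(1.0 - s.dice)
            assert soft_new_dice_loss(e, f) == pytest.approx(1.0 - s.new_dice)

    def test_false_positive_mass_penalized_harder_than_plain_dice(self):
        """Adding pure FP probability mass must lower soft new-dice by more
        than soft dice — the explicit over-segmentation penalty."""
        f = np.zeros((6, 6))
        f[2:4, 2:4] = 1.0
        base = f.copy()
        for delta in (0.1, 0.25, 0.5):
            e = base.copy()
            e[0, 0] = delta  # pure false positive
            drop_new = soft_new_dice_loss(e, f) - soft_new_dice_loss(base, f)
            drop_dice = soft_dice_loss(e, f) - soft_dice_loss(base, f)
            assert drop_new > drop_dice

    def test_out_of_range_probabilities_rejected(self):
        f = np.zeros((3, 3), dtype=int)
        f[0, 0] = 1
        with pytest.raises(ValidationError):
            soft_new_dice_loss(np.full((3, 3), 1.5), f)


class TestTextureFeatures:
    def test_constant_sample_is_degenerate(self):
        t = texture_features([4.2] * 10)
        assert t.degenerate
        assert t.mean == pytest.approx(4.2)
        assert (t.skewness, t.kurtosis) == (0.0, 0.0)

    def test_hand_computed_three_point_sample(self):
        t = texture_features([-1.0, 0.0, 1.0])
        assert t.mean == 0.0
        assert t.skewness == 0.0
        assert t.kurtosis == pytest.approx((2 / 3) / (4 / 9) - 3.0)  # -1.5

    def test_gaussian_sample_recovers_normal_moments(self):
        x = np.random.default_rng(123).standard_normal(1_000_000)
        t = texture_features(x)
        assert abs(t.skewness) < 0.01
        assert abs(t.kurtosis) < 0.02

    def test_affine_invariance_of_standardized_moments(self):
        x = np.random.default_rng(5).gamma(2.0, size=500)
        t0 = texture_features(x)
        t1 = texture_features(3.7 * x - 11.0)
        assert t1.skewness == pytest.approx(t0.skewness, abs=1e-9)
        assert t1.kurtosis == pytest.approx(t0.kurtosis, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            texture_features([])


class TestImageQuality:
    def _vol(self, arr, vr=(0.0, 255.0)):
        return ImageVolume(np.asarray(arr, float), value_range=vr)

    def test_identical_images(self):
        a = self._vol(np.random.default_rng(0).uniform(0, 255, (32, 32)))
        q = image_quality(a, a)
        assert q.rmse == 0.0 and q.psnr == float("inf")
        assert q.ssim == pytest.approx(1.0)

    def test_closed_form_constant_offset(self):
        ref = self._vol(np.zeros((16, 16)))
        test = self._vol(np.full((16, 16), 10.0))
        q = image_quality(ref, test, max_value=255.0)
        assert q.rmse == pytest.approx(10.0)
        assert q.psnr == pytest.approx(20 * np.log10(25.5), abs=1e-6)

    def test_psnr_rmse_identity(self):
        rng = np.random.default_rng(1)
        ref = self._vol(rng.uniform(0, 255, (32, 32)))
        test = self._vol(rng.uniform(0, 255, (32, 32)))
        q = image_quality(ref, test)
        assert q.psnr == pytest.approx(20 * np.log10(q.max_value / q.rmse),
                                       abs=1e-9)

    def test_psnr_decreases_with_noise_level(self, small_phantom):
        from strokeseg.core import NoiseModel
        from strokeseg.phantoms import add_lowdose_noise

        vol, _ = small_phantom
        psnrs = []
        for sigma in (5.0, 15.0, 25.0):
            pair = add_lowdose_noise(vol, NoiseModel(sigma=sigma, seed=8))
            psnrs.append(image_quality(vol, pair.noisy).psnr)
        assert psnrs[0] > psnrs[1] > psnrs[2]


class TestDetectionReport:
    def _masks(self, arrs):
        return [SegmentationMask(np.asarray(a, dtype=np.uint8)) for a in arrs]

    def test_perfect_prediction_scores_100(self):
        t = np.zeros((8, 8), dtype=int)
        t[2:4, 2:4] = 1
        rep = detection_report(self._masks([t]), self._masks([t]))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 100.0

    def test_all_background_prediction(self):
        t = np.zeros((8, 8), dtype=int)
        t[2:4, 2:4] = 1
        z = np.zeros((8, 8), dtype=int)
        rep = detection_report(self._masks([z]), self._masks([t]))
        assert rep.sensitivity == 0.0
        assert rep.specificity == 100.0

    def test_two_case_confusion_matrix_hand_check(self):
        t1 = np.zeros((4, 4), dtype=int); t1[0, :2] = 1        # 2 voxels
        p1 = np.zeros((4, 4), dtype=int); p1[0, 0] = 1         # TP1 FP0 FN1
        t2 = np.zeros((4, 4), dtype=int); t2[2, 2] = 1         # 1 voxel
        p2 = np.zeros((4, 4), dtype=int); p2[1, 1] = 1         # miss + 1 FP
        rep = detection_report(self._masks([p1, p2]), self._masks([t1, t2]))
        # voxel totals: TP=1, FP=1, FN=2, TN=28
        assert rep.accuracy == pytest.approx(100 * 29 / 32)
        assert rep.specificity == pytest.approx(100 * 28 / 29)
        # lesion level: 1 of 2 lesions detected
        assert rep.sensitivity == pytest.approx(50.0)
        assert rep.lesions_detected_mean == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        a = np.zeros((4, 4), dtype=int); a[0, 0] = 1
        b = np.zeros((5, 5), dtype=int); b[0, 0] = 1
        with pytest.raises(ValidationError):
            detection_report(self._masks([a]), self._masks([b]))


def _report_from_counts(counts, tp=10, fp=1, fn=1, tn=100):
    rows = [{"case": i, "true_lesions": 2, "detected_lesions": int(c),
             "tp": tp, "fp": fp, "fn": fn, "tn": tn}
            for i, c in enumerate(counts)]
    df = pd.DataFrame(rows)
    return EvalReport(100.0, 100.0, 100.0, float(np.mean(counts)),
                      float(np.std(counts, ddof=1)), per_case=df)


class TestGroupStatistics:
    def test_identical_groups_give_null_t(self):
        a = _report_from_counts([2, 2, 2, 2])
        b = _report_from_counts([2, 2, 2, 2])
        cmpres = compare_groups(a, b)
        assert cmpres.t_statistic == 0.0
        assert cmpres.t_pvalue == 1.0

    def test_chi_square_hand_computation(self):
        # margins: rows (100, 100), cols (60, 140), n = 200
        # E = [[30, 70], [30, 70]]; sum (O-E)^2/E = 2*(400/30 + 400/70)
        chi2, p = chi_square_2x2([[10, 90], [50, 50]])
        assert chi2 == pytest.approx(2 * (400 / 30 + 400 / 70), abs=1e-9)
        assert p < 1e-8

    def test_chi_square_agrees_with_enumerated_statistic_on_small_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tab = rng.integers(1, 21, size=(2, 2)).astype(float)
            chi2, _ = chi_square_2x2(tab)
            n = tab.sum()
            expected = 0.0
            for i in range(2):
                for j in range(2):
                    e = tab[i].sum() * tab[:, j].sum() / n
                    expected += (tab[i, j] - e) ** 2 / e
            assert chi2 == pytest.approx(expected, abs=1e-12)

    def test_type_one_error_rate_near_nominal(self):
        """Under the null (both groups from one generator) the Welch test
        should reject at ~5%."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = _report_from_counts(rng.normal(1.5, 0.4, size=20))
            b = _report_from_counts(rng.normal(1.5, 0.4, size=20))
            if compare_groups(a, b).t_pvalue < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_small_groups_rejected(self):
        a = _report_from_counts([2])
        with pytest.raises(ValidationError):
            compare_groups(a, a)


class TestBiasVariance:
    def _vol(self, arr):
        return ImageVolume(np.asarray(arr, float), value_range=(0, 255))

    def test_perfect_replicates(self):
        ref = self._vol(np.random.default_rng(0).uniform(0, 255, (8, 8)))
        rep = bias_variance([ref.data.copy(), ref.data.copy()], ref)
        assert (rep.bias_sq, rep.variance, rep.mse) == (0.0, 0.0, 0.0)

    def test_symmetric_deviation(self):
        ref = self._vol(np.full((8, 8), 50.0))
        rep = bias_variance([ref.data + 1.0, ref.data - 1.0], ref)
        assert rep.bias_sq == pytest.approx(0.0)
        assert rep.variance == pytest.approx(1.0)
        assert rep.mse == pytest.approx(1.0)

    def test_constant_offset(self):
        ref = self._vol(np.zeros((4, 4)))
        rep = bias_variance([ref.data + 3.0, ref.data + 3.0, ref.data + 3.0], ref)
        assert rep.bias_sq == pytest.approx(9.0)
        assert rep.variance == pytest.approx(0.0)

    def test_decomposition_identity_on_random_replicates(self):
        rng = np.random.default_rng(4)
        ref = self._vol(rng.uniform(0, 255, (16, 16)))
        reps = [ref.data + rng.standard_normal((16, 16)) * 5 for _ in range(6)]
        rep = bias_variance(reps, ref)
        assert rep.mse == pytest.approx(rep.bias_sq + rep.variance, abs=1e-9)

    def test_single_replicate_rejected(self):
        ref = self._vol(np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            bias_variance([ref.data], ref)


class TestRenderers:
    def test_table_layouts(self):
        q = image_quality(ImageVolume(np.zeros((8, 8)), value_range=(0, 255)),
                          ImageVolume(np.ones((8, 8)), value_range=(0, 255)))
        dfq = render_quality_table([("BM3D", q)])
        assert list(dfq.columns) == ["Method", "PSNR", "RMSE", "SSIM"]
        rep = _report_from_counts([1, 2])
        dfe = render_efficacy_table([("observation", rep)])
        assert list(dfe.columns) == ["Group", "Sensitivity (%)",
                                     "Number of lesions detected", "Accuracy (%)"]
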