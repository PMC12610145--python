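"""Overlap metrics, surface distance, PSNR, ICC and ANOVA vs independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from aaaseg.metrics import (
    ConfusionCounts,
    confusion_counts,
    dsc,
    evaluate_masks,
    icc_2_1,
    jc,
    mcc,
    msd,
    one_way_anova,
    psnr,
    relative_improvement,
)


def brute_force_counts(pred, truth):
    tp = tn = fp = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], truth[i, j]
            if p and t:
                tp += 1
            elif not p and not t:
                tn += 1
            elif p and not t:
                fp += 1
            else:
                fn += 1
    return tp, tn, fp, fn


def brute_force_msd(pred, truth):
    ps = np.argwhere(pred)
    ts = np.argwhere(truth)
    total = 0.0
    for p in ps:
        total += min(np.hypot(*(p - t)) for t in ts)
    return total / len(ps)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[:2, :5] = True
        c = confusion_counts(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_complement_prediction(self):
        truth = np.zeros((4, 4), dtype=bool)
        truth[:2] = True
        c = confusion_counts(~truth, truth)
        assert c.tp == 0 and c.tn == 0 and c.fp == 8 and c.fn == 8

    def test_matches_pixel_loop_on_random_masks(self, rng):
        for _ in range(20):
            pred = rng.random((8, 8)) > 0.5
            truth = rng.random((8, 8)) > 0.5
            c = confusion_counts(pred, truth)
            assert (c.tp, c.tn, c.fp, c.fn) == brute_force_counts(pred, truth)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(np.zeros((3, 3)), np.zeros((4, 4)))


class TestOverlapMetrics:
    def test_mcc_values(self):
        assert mcc(ConfusionCounts(10, 90, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(2, 2, 1, 1)) == pytest.approx(1.0 / 3.0)
        # all-background prediction: a denominator factor is zero
        assert mcc(ConfusionCounts(0, 50, 0, 14)) == 0.0

    def test_dsc_values(self):
        assert dsc(ConfusionCounts(5, 5, 0, 0)) == 1.0
        assert dsc(ConfusionCounts(0, 0, 3, 4)) == 0.0
        assert dsc(ConfusionCounts(12, 0, 1, 2)) == pytest.approx(24.0 / 27.0)
        assert dsc(ConfusionCounts(0, 100, 0, 0)) == 1.0  # both masks empty

    def test_jc_from_dsc(self):
        assert jc(1.0) == 1.0
        assert jc(0.0) == 0.0
        assert jc(24.0 / 27.0) == pytest.approx(12.0 / 15.0)

    def test_jc_identity_with_set_jaccard(self, rng):
        # DSC/(2-DSC) == TP/(TP+FP+FN), an algebraic identity
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 30, 3)
            tn = int(rng.integers(0, 30))
            if tp + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), tn, int(fp), int(fn))
            assert jc(dsc(c)) == pytest.approx(tp / (tp + fp + fn))

    def test_symmetry(self, rng):
        pred = rng.random((8, 8)) > 0.4
        truth = rng.random((8, 8)) > 0.6
        assert mcc(confusion_counts(pred, truth)) == pytest.approx(
            mcc(confusion_counts(truth, pred))
        )
        assert dsc(confusion_counts(pred, truth)) == pytest.approx(
            dsc(confusion_counts(truth, pred))
        )


class TestMsd:
    def test_identical_masks(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:5, 2:5] = True
        assert msd(m, m) == 0.0

    def test_single_pixels_at_known_distance(self):
        pred = np.zeros((10, 10), dtype=bool)
        truth = np.zeros((10, 10), dtype=bool)
        pred[2, 2] = True
        truth[2, 7] = True
        assert msd(pred, truth) == pytest.approx(5.0)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            pred = rng.random((16, 16)) > 0.7
            truth = rng.random((16, 16)) > 0.7
            if not pred.any() or not truth.any():
                continue
            assert msd(pred, truth) == pytest.approx(brute_force_msd(pred, truth))

    def test_one_directional_asymmetry(self):
        pred = np.zeros((12, 12), dtype=bool)
        truth = np.zeros((12, 12), dtype=bool)
        pred[5, 5] = True
        truth[5, 5] = True
        truth[5, 9] = True
        assert msd(pred, truth) == 0.0  # every pred pixel lies on truth
        assert msd(truth, pred) == pytest.approx(2.0)  # but not conversely

    def test_pixel_spacing_scales_result(self):
        pred = np.zeros((10, 10), dtype=bool)
        truth = np.zeros((10, 10), dtype=bool)
        pred[2, 2] = True
        truth[2, 6] = True
        assert msd(pred, truth, pixel_spacing_mm=1.5) == pytest.approx(6.0)

    def test_empty_prediction_flagged(self):
        truth = np.zeros((8, 8), dtype=bool)
        truth[3, 3] = True
        with pytest.raises(ValueError, match="empty prediction"):
            msd(np.zeros((8, 8), dtype=bool), truth)
        with pytest.raises(ValueError, match="truth"):
            msd(truth, np.zeros((8, 8), dtype=bool))

    def test_symmetric_variant_is_symmetric(self, rng):
        pred = rng.random((16, 16)) > 0.6
        truth = rng.random((16, 16)) > 0.6
        a = msd(pred, truth, symmetric=True)
        b = msd(truth, pred, symmetric=True)
        assert a == pytest.approx(b)


class TestPsnr:
    def test_reference_points(self):
        assert psnr(0.01) == pytest.approx(20.0)
        assert psnr(1.0) == pytest.approx(0.0)
        assert psnr(0.04, peak=0.2) == pytest.approx(0.0)

    def test_halving_mse_adds_3dB(self):
        assert psnr(0.005) - psnr(0.01) == pytest.approx(10 * math.log10(2))

    def test_zero_mse_flagged_infinite(self):
        assert psnr(0.0) == math.inf


class TestAnova:
    def test_hand_computed_example(self):
        # SSB = 6 -> MSB = 3; SSW = 6 -> MSW = 1
        f, df, p = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)
        assert df == (2, 6)
        assert p == pytest.approx(float(sps.f.sf(3.0, 2, 6)))

    def test_degenerate_identical_groups(self):
        f, _, p = one_way_anova([[1, 1], [1, 1]])
        assert f == 0.0 and p == 1.0

    def test_shift_invariance(self, rng):
        groups = [rng.normal(i, 1, 12).tolist() for i in range(3)]
        f1, _, p1 = one_way_anova(groups)
        f2, _, p2 = one_way_anova([[v + 5.0 for v in g] for g in groups])
        assert f1 == pytest.approx(f2) and p1 == pytest.approx(p2)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i * 0.3, 1, 20) for i in range(4)]
        f, _, p = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], [3.0]])


class TestIcc:
    def test_identical_raters_give_one(self):
        ratings = np.tile(np.arange(10.0)[:, None], (1, 3))
        icc, _ = icc_2_1(ratings)
        assert icc == pytest.approx(1.0)

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(7)
        subj = rng.normal(0, 1, 500)
        ratings = subj[:, None] + rng.normal(0, 0.5, (500, 3))
        icc, (lo, hi) = icc_2_1(ratings)
        expected = 1.0 / (1.0 + 0.25)
        assert abs(icc - expected) < 0.05
        assert lo < icc < hi

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        n, k = 40, 4
        ratings = rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.6, (n, k)) + rng.normal(
            0, 0.3, (1, k)
        )
        icc, (lo, hi) = icc_2_1(ratings)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": ratings.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        ref_lo, ref_hi = row["CI95"]  # pingouin rounds its CI to 2 decimals
        assert round(lo, 2) == pytest.approx(ref_lo, abs=5e-3)
        assert round(hi, 2) == pytest.approx(ref_hi, abs=5e-3)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((10, 1)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_2_1(np.full((5, 3), 2.0))


class TestRelativeImprovement:
    def test_reported_filter_gains_recompute(self):
        # gains of the best filter arm over the noisy arm, from the
        # summary metric values
        assert relative_improvement(0.7070, 0.9268, "relative_to_before") == pytest.approx(
            31.09, abs=0.005
        )
        assert relative_improvement(0.6897, 0.9259, "relative_to_before") == pytest.approx(
            34.25, abs=0.005
        )
        assert relative_improvement(0.5631, 0.8671, "relative_to_before") == pytest.approx(
            53.99, abs=0.005
        )
        # surface distance improves by decreasing
        assert relative_improvement(83.06, 80.10, "relative_to_after") == pytest.approx(
            3.70, abs=0.005
        )

    def test_no_change_is_zero(self):
        assert relative_improvement(0.5, 0.5, "relative_to_before") == 0.0

    def test_difference_mode_in_points(self):
        assert relative_improvement(78.47, 100.0, "difference") == pytest.approx(21.53)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            relative_improvement(0.0, 1.0, "relative_to_before")
        with pytest.raises(ValueError):
            relative_improvement(1.0, 0.0, "relative_to_after")


def test_evaluate_masks_tolerates_empty_predictions(rng):
    truth = [np.zeros((8, 8), dtype=np.uint8) for _ in range(2)]
    truth[0][2:4, 2:4] = 1
    truth[1][5:7, 5:7] = 1
    pred = [truth[0].copy(), np.zeros((8, 8), dtype=np.uint8)]
    rep = evaluate_masks(pred, truth)
    assert rep.dsc[0] == 1.0 and rep.dsc[1] == 0.0
    assert math.isnan(rep.msd[1])
    assert rep.means()["msd"] == 0.0
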