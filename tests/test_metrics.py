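import math

import numpy as np
import pytest

from sagru.metrics import (
    DegenerateTTestError,
    abs_error_summary,
    clarke_zone,
    clarke_zone_counts,
    clarke_zones,
    classification_metrics,
    evaluate_predictions,
    mae,
    mard,
    mean_sd,
    paired_t_test,
    rmse,
)


class TestPointMetrics:
    def test_perfect_prediction_is_zero(self):
        x = [100.0, 150.0, 70.0]
        assert rmse(x, x) == 0.0
        assert mae(x, x) == 0.0
        assert mard(x, x) == 0.0

    def test_hand_examples(self):
        assert rmse([110, 90], [100, 100]) == pytest.approx(10.0)
        assert mae([110, 90], [100, 100]) == pytest.approx(10.0)
        assert mae([101], [100]) == pytest.approx(1.0)
        assert mard([69.6], [69.97]) == pytest.approx(abs(69.6 - 69.97) / 69.97 * 100)
        assert mard([200], [100]) == pytest.approx(100.0)

    def test_matches_one_line_recomputation(self, rng):
        p = rng.uniform(40, 400, 1000)
        r = rng.uniform(40, 400, 1000)
        assert rmse(p, r) == pytest.approx(float(np.sqrt(((p - r) ** 2).mean())), abs=1e-10)
        assert mae(p, r) == pytest.approx(float(np.abs(p - r).mean()), abs=1e-10)
        assert mard(p, r) == pytest.approx(float((np.abs(p - r) / r).mean() * 100), abs=1e-10)

    def test_rmse_dominates_mae(self, rng):
        for _ in range(20):
            p = rng.uniform(40, 400, 50)
            r = rng.uniform(40, 400, 50)
            assert rmse(p, r) >= mae(p, r) - 1e-12

    def test_scale_behavior(self, rng):
        p = rng.uniform(40, 400, 100)
        r = rng.uniform(40, 400, 100)
        assert rmse(2 * p, 2 * r) == pytest.approx(2 * rmse(p, r))
        assert mae(2 * p, 2 * r) == pytest.approx(2 * mae(p, r))
        assert mard(2 * p, 2 * r) == pytest.approx(mard(p, r))

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            mard([100.0], [0.0])


def oracle_clarke_zone(ref, pred):
    """Scalar region-membership oracle for the canonical error grid,
    written as an explicit decision list with integer-scaled arithmetic."""
    x, y = float(ref), float(pred)
    if x <= 70 and y <= 70:
        return "A"
    if 5 * abs(y - x) <= x:
        return "A"
    if x >= 180 and y <= 70:
        return "E"
    if x <= 70 and y >= 180:
        return "E"
    if 70 <= x <= 290 and y - x >= 110:
        return "C"
    if 130 <= x <= 180 and 5 * y <= 7 * x - 910:
        return "C"
    if x >= 240 and 70 <= y <= 180:
        return "D"
    if 3 * x <= 175 and 70 <= y <= 180:
        return "D"
    if 175 <= 3 * x <= 210 and 5 * y >= 6 * x:
        return "D"
    return "B"


class TestClarkeGrid:
    @pytest.mark.parametrize("pred, ref, zone", [
        (200.0, 200.0, "A"),   # diagonal
        (115.0, 100.0, "A"),   # within 20 percent
        (60.0, 200.0, "E"),    # hyper measured, hypo predicted
        (250.0, 100.0, "C"),   # large overprediction
        (100.0, 250.0, "D"),   # missed hyperglycemia
        (150.0, 100.0, "B"),
    ])
    def test_representative_points(self, pred, ref, zone):
        assert clarke_zone(pred, ref) == zone

    def test_diagonal_is_always_zone_a(self, rng):
        v = rng.uniform(1, 550, 200)
        assert set(clarke_zones(v, v)) == {"A"}

    def test_counts_sum_to_n(self, rng):
        p = rng.uniform(1, 550, 500)
        r = rng.uniform(1, 550, 500)
        counts = clarke_zone_counts(p, r)
        assert sum(counts.values()) == 500

    def test_lattice_matches_membership_oracle(self):
        # every integer (reference, prediction) pair on [1, 550]^2
        grid = np.arange(1.0, 551.0)
        R, P = np.meshgrid(grid, grid, indexing="ij")
        zones = clarke_zones(P.ravel(), R.ravel())
        expected = np.array(
            [oracle_clarke_zone(x, y) for x, y in zip(R.ravel(), P.ravel())],
            dtype=object,
        )
        mismatch = zones != expected
        assert not mismatch.any(), (
            f"{mismatch.sum()} lattice points disagree, first at "
            f"ref={R.ravel()[mismatch][0]}, pred={P.ravel()[mismatch][0]}"
        )

    def test_positive_input_required(self):
        with pytest.raises(ValueError):
            clarke_zone(0.0, 100.0)


class TestClassificationMetrics:
    def test_perfect(self):
        acc, prec, rec = classification_metrics([True, False], [True, False])
        assert (acc, prec, rec) == (100.0, 100.0, 100.0)

    def test_hand_counts(self):
        # TP=1, FP=1, FN=0, TN=2
        pred = [True, True, False, False]
        ref = [True, False, False, False]
        acc, prec, rec = classification_metrics(pred, ref)
        assert acc == pytest.approx(75.0)
        assert prec == pytest.approx(50.0)
        assert rec == pytest.approx(100.0)

    def test_all_negative_predictions_zero_recall(self):
        acc, prec, rec = classification_metrics([False, False], [True, False])
        assert rec == 0.0
        assert prec is None  # no predicted positives -> undefined, not 0

    def test_no_reference_positives_undefined_recall(self):
        _, _, rec = classification_metrics([False, True], [False, False])
        assert rec is None


class TestErrorSummary:
    def test_zero_errors(self):
        s = abs_error_summary([100.0, 90.0], [100.0, 90.0])
        assert s.min == s.q1 == s.median == s.q3 == s.p95 == s.max == s.sd == 0.0

    def test_hand_quantiles(self):
        s = abs_error_summary([101, 102, 103, 104, 105], [100] * 5)
        assert s.median == 3.0
        assert s.q1 == 2.0
        assert s.q3 == 4.0
        assert s.min == 1.0 and s.max == 5.0

    def test_sd_matches_two_pass_formula(self, rng):
        p = rng.uniform(40, 400, 200)
        r = rng.uniform(40, 400, 200)
        e = np.abs(p - r)
        mean = e.sum() / len(e)
        sd = math.sqrt(((e - mean) ** 2).sum() / (len(e) - 1))
        assert abs_error_summary(p, r).sd == pytest.approx(sd, abs=1e-10)

    def test_ordering_invariant(self, rng):
        s = abs_error_summary(rng.uniform(40, 400, 64), rng.uniform(40, 400, 64))
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.p95 <= s.max


class TestPairedTTest:
    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateTTestError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_difference_degenerate(self):
        with pytest.raises(DegenerateTTestError):
            paired_t_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(5, 1, 10)
        b = rng.normal(5.5, 1, 10)
        t, p = paired_t_test(a, b)
        d = a - b
        n = len(d)
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        from scipy.stats import t as tdist

        p_ref = 2 * tdist.sf(abs(t_ref), df=n - 1)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestEvaluatePredictions:
    def test_report_is_internally_consistent(self, rng):
        ref = rng.uniform(45, 350, 400)
        pred = ref + rng.normal(0, 12, 400)
        pred = np.clip(pred, 40, 500)
        report = evaluate_predictions(pred, ref)
        assert report.n == 400
        assert sum(report.clarke_counts.values()) == 400
        assert report.rmse >= report.mae >= 0
        assert 0 <= report.accuracy <= 100
        row = report.to_row(variant="sagru")
        assert row["variant"] == "sagru"
        assert row["zone_A"] == report.clarke_counts["A"]

    def test_mean_sd(self):
        m, s = mean_sd([1.0, 2.0, 3.0])
        assert m == 2.0 and s == 1.0
        assert mean_sd([5.0]) == (5.0, 0.0)
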