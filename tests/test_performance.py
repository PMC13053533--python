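"""Discrimination and calibration metrics."""

import numpy as np
import pytest
from scipy.special import expit, logit

from extval import performance
from extval.performance import (
    auc,
    auc_point,
    calibrate_metrics,
    calibration_curve,
    calibration_slope,
    citl,
    classify_discrimination,
    eo_ratio,
)


def brute_force_auc(p, y):
    """O(n^2) all-pairs concordance count, ties counted half."""
    p, y = np.asarray(p), np.asarray(y)
    cases, controls = p[y == 1], p[y == 0]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_point([0.2, 0.8], [0, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_point([0.3] * 10, [0, 1] * 5) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 300))
        p = rng.choice(np.round(rng.uniform(size=40), 2), size=n)  # force ties
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auc_point(p, y) == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        y = rng.integers(0, 2, size=500)
        assert auc_point(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.01, 0.99, size=400)
        y = (rng.uniform(size=400) < p).astype(int)
        base = auc_point(p, y)
        for f in (lambda x: x**3, lambda x: expit(5 * logit(x)), lambda x: 2 * x + 1):
            assert auc_point(f(p), y) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_point([0.1, 0.2], [1, 1])

    def test_ci_brackets_point_within_unit_interval(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=300)
        y = (rng.uniform(size=300) < p).astype(int)
        r = auc(p, y)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0


class TestBanding:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.75, "acceptable"),
            (0.82, "excellent"),
            (0.95, "outstanding"),
            (0.65, "poor"),
            (0.70, "acceptable"),
            (0.80, "excellent"),
            (0.90, "outstanding"),
        ],
    )
    def test_hosmer_bands(self, value, band):
        assert classify_discrimination(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_discrimination(1.2)


class TestEORatio:
    def test_predictions_summing_to_events_give_one(self):
        p = [0.25, 0.25, 0.25, 0.25]
        y = [1, 0, 0, 0]
        assert eo_ratio(p, y) == 1.0

    def test_arithmetic(self):
        assert eo_ratio([0.5] * 4, [1, 0, 0, 0]) == 2.0

    def test_ratio_identity_exact(self, val_spec, dev_spec):
        import extval

        df = extval.generate_cohort(val_spec)
        p = dev_spec.truth_model.predicted_risk(df)
        cal = calibrate_metrics(p, df.outcome.to_numpy())
        assert cal.eo == cal.n_expected / cal.n_observed
        assert cal.interpretation in ("overprediction", "underprediction", "perfect agreement")

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            eo_ratio([0.1, 0.2], [0, 0])


class TestCitl:
    def test_constant_prediction_closed_form(self):
        # offset is logit(p0); the fitted intercept must be logit(rate)-logit(p0)
        y = np.r_[np.ones(20), np.zeros(80)]
        p0 = 0.3
        a, _ = citl(np.full(100, p0), y)
        assert a == pytest.approx(float(logit(0.2) - logit(p0)), abs=1e-8)

    def test_offset_inflated_by_one_gives_minus_one(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        truth = 0.3
        inflated = float(expit(logit(truth) + 1.0))
        a, _ = citl(np.full(100, inflated), y)
        assert a == pytest.approx(-1.0, abs=1e-8)

    def test_self_consistent_predictions_give_zero(self):
        rng = np.random.default_rng(12)
        n = 100_000
        p = expit(rng.normal(-2.0, 1.5, size=n))
        y = (rng.uniform(size=n) < p).astype(int)
        a, _ = citl(p, y)
        se = 1 / np.sqrt(np.sum(p * (1 - p)))
        assert a == pytest.approx(0.0, abs=3 * se)


class TestCalibrationSlope:
    def test_parameter_recovery_slope_two(self):
        rng = np.random.default_rng(21)
        n = 100_000
        lp = rng.normal(-2.0, 1.0, size=n)
        y = (rng.uniform(size=n) < expit(2.0 * lp)).astype(int)
        b, (lo, hi) = calibration_slope(expit(lp), y)
        assert lo <= 2.0 <= hi
        assert b == pytest.approx(2.0, abs=3 * (hi - b) / 1.96)

    def test_self_consistency_slope_one(self):
        rng = np.random.default_rng(22)
        n = 100_000
        p = expit(rng.normal(-2.0, 1.5, size=n))
        y = (rng.uniform(size=n) < p).astype(int)
        b, (lo, hi) = calibration_slope(p, y)
        assert lo <= 1.0 <= hi

    def test_two_point_algebraic_solution(self):
        # two distinct prediction values with group event rates r0, r1: the
        # saturated two-parameter logistic fit passes through both, so
        # slope = (logit r1 - logit r0) / (lp1 - lp0)
        p = np.r_[np.full(40, 0.2), np.full(60, 0.6)]
        y = np.r_[np.ones(10), np.zeros(30), np.ones(30), np.zeros(30)]
        b, _ = calibration_slope(p, y)
        expected = float(
            (logit(0.5) - logit(0.25)) / (logit(0.6) - logit(0.2))
        )
        assert b == pytest.approx(expected, abs=1e-7)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError):
            calibration_slope([0.3] * 10, [0, 1] * 5)


class TestCalibrationCurve:
    def test_perfectly_calibrated_bins_near_diagonal(self):
        rng = np.random.default_rng(31)
        n = 50_000
        p = expit(rng.normal(-2.0, 1.5, size=n))
        y = (rng.uniform(size=n) < p).astype(int)
        curve = calibration_curve(p, y, "deciles")
        inside = (curve.ci_low <= curve.predicted) & (curve.predicted <= curve.ci_high)
        assert inside.mean() >= 0.8
        assert curve.counts.sum() == n

    def test_overprediction_pattern_above_point_two(self):
        # miscalibration imposed on the risk scale (true logit = a + b*lp with
        # b = 0.536 and a chosen so CITL ~ -0.44): observed proportions fall
        # below the diagonal wherever predicted risk exceeds 0.2
        rng = np.random.default_rng(32)
        n = 60_000
        lp = rng.normal(-2.0, 1.5, size=n)
        p_pred = expit(lp)
        p_true = expit(-0.95 + 0.536 * lp)
        y = (rng.uniform(size=n) < p_true).astype(int)
        cal = calibrate_metrics(p_pred, y)
        assert cal.citl == pytest.approx(-0.439, abs=0.05)
        assert cal.slope == pytest.approx(0.536, abs=0.05)
        assert cal.eo > 1.0
        curve = calibration_curve(p_pred, y, "deciles")
        high = curve.predicted > 0.2
        assert high.any()
        assert (curve.observed[high] < curve.predicted[high]).all()

    def test_concentrated_predictions_error_path(self):
        with pytest.raises(ValueError):
            calibration_curve([0.2] * 100, [0, 1] * 50, "deciles")

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.1, 0.9] * 5, [0, 1] * 5, "deciles")

    def test_smoother_returns_grid_in_unit_interval(self):
        rng = np.random.default_rng(33)
        p = rng.uniform(0.01, 0.6, size=2000)
        y = (rng.uniform(size=2000) < p).astype(int)
        curve = calibration_curve(p, y, "smoother")
        assert curve.method == "smoother"
        assert ((curve.observed >= 0) & (curve.observed <= 1)).all()


class TestDelongCoverage:
    def test_empirical_coverage_near_nominal(self):
        # 500 seeded replicates at n=500, prevalence 0.11
        rng = np.random.default_rng(99)
        hits, reps = 0, 500
        # establish the true AUC of the generating mechanism once, at large n
        lp = rng.normal(logit(0.11), 1.2, size=400_000)
        y0 = (rng.uniform(size=400_000) < expit(lp)).astype(int)
        true_auc = auc_point(expit(lp), y0)
        for _ in range(reps):
            lp = rng.normal(logit(0.11), 1.2, size=500)
            y = (rng.uniform(size=500) < expit(lp)).astype(int)
            if y.min() == y.max():
                continue
            r = auc(expit(lp), y)
            hits += r.ci_low <= true_auc <= r.ci_high
        coverage = hits / reps
        assert 0.92 <= coverage <= 0.98
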