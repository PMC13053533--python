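"""Model updating: recalibration identities, re-estimation, recommendations."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import expit

import extval
from extval import (
    recalibrate_intercept,
    recalibrate_slope,
    reestimate,
    interpret_validation,
)
from extval.performance import (
    CalibrationResult,
    DiscriminationResult,
    auc_point,
    calibrate_metrics,
)


@pytest.fixture(scope="module")
def fitting_setup(dev_spec, val_spec):
    cohort = extval.generate_cohort(val_spec)
    return dev_spec.truth_model, cohort


class TestRecalibrateIntercept:
    def test_score_identity_eo_one_citl_zero(self, fitting_setup):
        model, cohort = fitting_setup
        up = recalibrate_intercept(model, cohort)
        p = up.predicted_risk(cohort)
        y = cohort.outcome.to_numpy()
        cal = calibrate_metrics(p, y)
        assert cal.eo == pytest.approx(1.0, abs=1e-6)
        assert cal.citl == pytest.approx(0.0, abs=1e-6)
        assert np.sum(p) == pytest.approx(np.sum(y), abs=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_identities_hold_on_any_seeded_cohort(self, dev_spec, seed):
        vs = extval.validation_spec(seed=500 + seed, dev=dev_spec)
        cohort = extval.generate_cohort(vs)
        up = recalibrate_intercept(dev_spec.truth_model, cohort)
        cal = calibrate_metrics(up.predicted_risk(cohort), cohort.outcome.to_numpy())
        assert round(cal.eo, 3) == 1.0
        assert round(cal.citl, 3) == 0.0

    def test_already_calibrated_alpha_near_zero(self, dev_spec):
        cohort = extval.generate_cohort(replace(dev_spec, n=50_000, seed=81))
        up = recalibrate_intercept(dev_spec.truth_model, cohort)
        assert up.alpha == pytest.approx(0.0, abs=0.1)

    def test_slope_remains_below_one_on_overfit_cohort(self, fitting_setup):
        model, cohort = fitting_setup
        up = recalibrate_intercept(model, cohort)
        cal = calibrate_metrics(up.predicted_risk(cohort), cohort.outcome.to_numpy())
        assert cal.slope < 1.0

    def test_beta_fixed_at_one(self, fitting_setup):
        model, cohort = fitting_setup
        assert recalibrate_intercept(model, cohort).beta == 1.0


class TestRecalibrateSlope:
    def test_full_identities(self, fitting_setup):
        model, cohort = fitting_setup
        up = recalibrate_slope(model, cohort)
        cal = calibrate_metrics(up.predicted_risk(cohort), cohort.outcome.to_numpy())
        assert cal.eo == pytest.approx(1.0, abs=1e-6)
        assert cal.citl == pytest.approx(0.0, abs=1e-6)
        assert cal.slope == pytest.approx(1.0, abs=1e-6)

    def test_out_of_sample_recovery(self, dev_spec):
        # the generator flattens true risk with slope 0.536; recalibrating on
        # one large cohort should give calibrated predictions on a fresh one
        fit_spec = extval.validation_spec(seed=601, dev=dev_spec)
        fit = extval.generate_cohort(replace(fit_spec, n=100_000))
        fresh = extval.generate_cohort(replace(fit_spec, seed=602, n=100_000))
        up = recalibrate_slope(dev_spec.truth_model, fit)
        assert up.beta == pytest.approx(0.536, abs=0.05)
        b, (lo, hi) = extval.calibration_slope(
            up.predicted_risk(fresh), fresh.outcome.to_numpy()
        )
        assert lo - 3 * (b - lo) / 1.96 <= 1.0 <= hi + 3 * (hi - b) / 1.96

    def test_idempotent_fixed_point(self, fitting_setup):
        model, cohort = fitting_setup
        up = recalibrate_slope(model, cohort)
        recalibrated = extval.LogisticPredictionModel(
            up.alpha + up.beta * model.intercept,
            {k: up.beta * v for k, v in model.coefficients.items()},
            model.predictors,
        )
        again = recalibrate_slope(recalibrated, cohort)
        assert again.alpha == pytest.approx(0.0, abs=1e-5)
        assert again.beta == pytest.approx(1.0, abs=1e-5)

    def test_constant_lp_rejected(self, fitting_setup):
        model, cohort = fitting_setup
        flat = extval.LogisticPredictionModel(-2.0, {})
        with pytest.raises(ValueError):
            recalibrate_slope(flat, cohort)


class TestDiscriminationInvariance:
    def test_updating_never_changes_auc(self, fitting_setup):
        model, cohort = fitting_setup
        y = cohort.outcome.to_numpy()
        base = auc_point(model.predicted_risk(cohort), y)
        for update in (recalibrate_intercept, recalibrate_slope):
            up = update(model, cohort)
            assert auc_point(up.predicted_risk(cohort), y) == pytest.approx(
                base, abs=1e-12
            )


class TestReestimate:
    def test_parameter_recovery_at_large_n(self, dev_spec):
        big = extval.generate_cohort(replace(dev_spec, n=100_000, seed=91))
        up = reestimate(dev_spec.truth_model, big)
        truth = dev_spec.truth_model
        for name, b in truth.coefficients.items():
            assert up.coefficients[name] == pytest.approx(b, abs=max(0.03, 0.1 * abs(b)))
        # the intercept trades off against high-mean predictors (temperature
        # ~37 with SD 0.65), so recovery is asserted in prediction space
        p_fit = up.predicted_risk(big)
        p_true = truth.predicted_risk(big)
        assert np.mean(np.abs(p_fit - p_true)) < 0.005

    def test_apparent_slope_exactly_one(self, fitting_setup):
        model, cohort = fitting_setup
        up = reestimate(model, cohort)
        b, _ = extval.calibration_slope(
            up.predicted_risk(cohort), cohort.outcome.to_numpy()
        )
        assert b == pytest.approx(1.0, abs=1e-6)
        assert up.apparent

    def test_zero_effect_predictor_ci_covers_zero(self, dev_spec):
        # a predictor with no true effect: its refitted CI should cover 0 at
        # roughly the nominal rate over replicates
        from extval.performance import fit_logistic

        covered, reps = 0, 60
        truth = extval.LogisticPredictionModel(-2.0, {"a": 0.8, "b": 0.0})
        rng = np.random.default_rng(95)
        for _ in range(reps):
            import pandas as pd

            n = 1500
            df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
            p = truth.predicted_risk(df)
            df["outcome"] = (rng.uniform(size=n) < p).astype(int)
            res = fit_logistic(df.outcome.to_numpy(), df[["a", "b"]].to_numpy())
            lo = res.params[2] - 1.96 * res.bse[2]
            hi = res.params[2] + 1.96 * res.bse[2]
            covered += lo <= 0.0 <= hi
        rate = covered / reps
        assert 0.85 <= rate <= 1.0

    def test_too_few_events_rejected(self, dev_spec):
        small = extval.generate_cohort(replace(dev_spec, n=30, seed=96))
        small["outcome"] = 0
        small.loc[0, "outcome"] = 1
        with pytest.raises(ValueError, match="events"):
            reestimate(dev_spec.truth_model, small)


class TestInterpretValidation:
    @staticmethod
    def _cal(citl, citl_ci, slope, slope_ci, eo=1.0):
        o = 100
        return CalibrationResult(
            eo=eo, eo_ci=(eo * 0.9, eo * 1.1), citl=citl, citl_ci=citl_ci,
            slope=slope, slope_ci=slope_ci, n_expected=eo * o, n_observed=o,
        )

    @staticmethod
    def _disc(a):
        return DiscriminationResult(
            auc=a, ci_low=a - 0.05, ci_high=a + 0.05,
            band=extval.classify_discrimination(a), n_events=100, n_nonevents=800,
        )

    def test_published_miscalibration_calls_for_slope_update(self):
        cal = self._cal(-0.439, (-0.63, -0.25), 0.536, (0.41, 0.66), eo=1.335)
        rec = interpret_validation(cal, self._disc(0.75))
        assert rec["recommendation"] == "intercept+slope"

    def test_perfect_metrics_no_update(self):
        cal = self._cal(0.0, (-0.2, 0.2), 1.0, (0.8, 1.2))
        assert interpret_validation(cal, self._disc(0.75))["recommendation"] == "none"

    def test_citl_off_slope_fine_intercept_only(self):
        cal = self._cal(-0.4, (-0.6, -0.2), 0.95, (0.75, 1.15))
        assert interpret_validation(cal, self._disc(0.75))["recommendation"] == "intercept"

    def test_everything_off_with_poor_discrimination(self):
        cal = self._cal(-0.5, (-0.7, -0.3), 0.5, (0.4, 0.6))
        rec = interpret_validation(cal, self._disc(0.62))
        assert rec["recommendation"] == "consider-reestimation"
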