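"""Model updating (step 3): recalibration and coefficient re-estimation.

When a transported model miscalibrates in the validation setting, it can be
updated in increasing order of aggressiveness:

* *intercept recalibration* — refit only an additive correction ``alpha``
  with the base linear predictor (LP) held as an offset. At convergence the
  score equation forces the sum of updated predictions to equal the number
  of observed events, so E:O = 1 and CITL = 0 on the fitting cohort;
* *intercept + slope recalibration* — a two-parameter logistic fit of the
  outcome on the base LP; on the fitting cohort E:O = 1, CITL = 0 and
  calibration slope = 1 hold as score-equation identities;
* *re-estimation* — a full logistic refit of all predictor coefficients;
  its apparent performance is optimistic and flagged as such.

Neither recalibration changes discrimination: the updated LP is a strictly
monotone transform of the base LP, so the AUC is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import performance
from .model import LogisticPredictionModel, OUTCOME_COL, clip_risk

__all__ = [
    "UpdatedModel",
    "recalibrate_intercept",
    "recalibrate_slope",
    "reestimate",
    "interpret_validation",
]


@dataclass(frozen=True)
class UpdatedModel:
    """Recalibration layer on a base model.

    For kinds ``intercept`` and ``intercept+slope`` the updated prediction is
    ``expit(alpha + beta * LP_base)`` with ``beta = 1`` for intercept-only.
    For ``re-estimated`` the coefficients are refit outright.
    """

    base: LogisticPredictionModel
    kind: str
    alpha: float
    beta: float = 1.0
    coefficients: Mapping[str, float] | None = None
    separation_flag: bool = False
    apparent: bool = False  # metrics on the fitting data are optimistic

    def __post_init__(self) -> None:
        if self.kind not in ("intercept", "intercept+slope", "re-estimated"):
            raise ValueError(f"unknown update kind {self.kind!r}")
        if self.kind == "intercept" and self.beta != 1.0:
            raise ValueError("intercept-only update must keep beta = 1")

    def linear_predictor(self, records) -> np.ndarray:
        if self.kind == "re-estimated":
            refit = LogisticPredictionModel(
                self.alpha, dict(self.coefficients), self.base.predictors,
                label=f"{self.base.label}|re-estimated",
            )
            return refit.linear_predictor(records)
        return self.alpha + self.beta * np.asarray(self.base.linear_predictor(records))

    def predicted_risk(self, records) -> np.ndarray:
        return clip_risk(expit(self.linear_predictor(records)))


def recalibrate_intercept(
    model: LogisticPredictionModel, records: pd.DataFrame, outcome_col: str = OUTCOME_COL
) -> UpdatedModel:
    """Intercept-only update: logistic fit with the base LP as fixed offset."""
    y = records[outcome_col].to_numpy(dtype=float)
    _check_two_classes(y)
    lp = np.asarray(model.linear_predictor(records), dtype=float)
    res = performance.fit_logistic(y, None, offset=lp)
    return UpdatedModel(model, "intercept", alpha=float(res.params[0]))


def recalibrate_slope(
    model: LogisticPredictionModel, records: pd.DataFrame, outcome_col: str = OUTCOME_COL
) -> UpdatedModel:
    """Joint intercept + slope update: two-parameter logistic fit on the LP."""
    y = records[outcome_col].to_numpy(dtype=float)
    _check_two_classes(y)
    lp = np.asarray(model.linear_predictor(records), dtype=float)
    if np.ptp(lp) == 0:
        raise ValueError("constant base LP: slope unidentifiable")
    res = performance.fit_logistic(y, lp[:, None])
    return UpdatedModel(
        model, "intercept+slope", alpha=float(res.params[0]), beta=float(res.params[1])
    )


def reestimate(
    model: LogisticPredictionModel,
    records: pd.DataFrame,
    outcome_col: str = OUTCOME_COL,
    min_events: int = 10,
) -> UpdatedModel:
    """Full refit of the model's predictors on the validation cohort.

    Guarded by a minimum event count; (quasi-)separation is flagged on the
    result rather than raised. Apparent in-sample metrics of the refit are
    optimistic, which the ``apparent`` flag records.
    """
    y = records[outcome_col].to_numpy(dtype=float)
    _check_two_classes(y)
    if int(y.sum()) < min_events:
        raise ValueError(f"fewer than {min_events} events; refit would be unstable")
    names = list(model.coefficients)
    X = records[names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("predictors contain missing values; impute first")
    flagged = False
    try:
        res = performance.fit_logistic(y, X)
        params = np.asarray(res.params, dtype=float)
        prob = np.asarray(res.predict())
        if np.max(np.abs(params)) > 1e3 or prob.min() < 1e-10 or prob.max() > 1 - 1e-10:
            flagged = True
    except Exception:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e4, max_iter=5000)
        clf.fit(X, y)
        params = np.r_[clf.intercept_, clf.coef_.ravel()]
        flagged = True
    coefs = dict(zip(names, params[1:]))
    return UpdatedModel(
        model, "re-estimated", alpha=float(params[0]), beta=1.0,
        coefficients=coefs, separation_flag=flagged, apparent=True,
    )


def interpret_validation(
    calibration: "performance.CalibrationResult",
    discrimination: "performance.DiscriminationResult",
    relatedness=None,
) -> dict:
    """Rule-based updating recommendation from step-1/2 results.

    Rules (95% CIs against the null values): CITL CI excluding 0 calls for an
    intercept update; slope CI excluding 1 calls for intercept + slope;
    both together with poor discrimination suggest considering full
    re-estimation; otherwise no update.
    """
    citl_off = not (calibration.citl_ci[0] <= 0.0 <= calibration.citl_ci[1])
    slope_off = not (calibration.slope_ci[0] <= 1.0 <= calibration.slope_ci[1])
    poor = discrimination.band == "poor"
    if slope_off and citl_off and poor:
        rec = "consider-reestimation"
    elif slope_off:
        rec = "intercept+slope"
    elif citl_off:
        rec = "intercept"
    else:
        rec = "none"
    return {
        "recommendation": rec,
        "rules": {
            "citl_ci_excludes_0": citl_off,
            "slope_ci_excludes_1": slope_off,
            "discrimination_poor": poor,
        },
        "relatedness_verdict": getattr(relatedness, "verdict", None),
    }


def _check_two_classes(y: np.ndarray) -> None:
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
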