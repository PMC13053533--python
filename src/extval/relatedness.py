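"""Case-mix relatedness between development and validation cohorts (step 1).

Two diagnostics decide whether a validation cohort is plausibly drawn from
the same population the model was developed in:

* the *membership model* — a logistic regression of cohort membership
  (development vs validation) on the model's predictors plus the outcome.
  Its apparent AUC measures how separable the cohorts are: ~0.5 means
  exchangeable case mix, values toward 1 mean strongly different settings;
* a comparison of the scored model's linear-predictor distribution in the
  two cohorts: a two-sample t-test on the means and an F variance-ratio
  test (Levene optional) on the spreads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import performance
from .model import LogisticPredictionModel, OUTCOME_COL

__all__ = ["RelatednessResult", "LPComparison", "membership_auc", "compare_lp", "assess_relatedness"]


@dataclass(frozen=True)
class RelatednessResult:
    """Membership-model discrimination plus its interpretation."""

    auc: float
    ci_low: float
    ci_high: float
    verdict: str
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.5 <= self.auc <= 1.0:
            raise ValueError("membership AUC must be orientation-normalized to [0.5, 1]")


@dataclass(frozen=True)
class LPComparison:
    mean_dev: float
    mean_val: float
    sd_dev: float
    sd_val: float
    t_statistic: float
    t_pvalue: float
    variance_statistic: float
    variance_pvalue: float
    variance_test: str


def _verdict(auc_value: float) -> str:
    # interpretive convenience: the verbal mapping of membership AUC to
    # "similar" / "related but different" / "different" settings
    if auc_value < 0.6:
        return "similar"
    if auc_value <= 0.8:
        return "related-but-different"
    return "different"


def membership_auc(
    dev: pd.DataFrame,
    val: pd.DataFrame,
    covariates: Sequence[str],
) -> RelatednessResult:
    """Apparent AUC of the cohort-membership logistic model.

    ``covariates`` should be the prediction model's predictors plus the
    outcome column; both cohorts must be complete in them (impute first).
    The AUC is orientation-normalized to at least 0.5 (swapping the cohort
    labels leaves the result unchanged). Perfect or quasi-perfect separation
    is flagged rather than raised.
    """
    if len(dev) == 0 or len(val) == 0:
        raise ValueError("both cohorts must be non-empty")
    X = pd.concat([dev[list(covariates)], val[list(covariates)]], ignore_index=True)
    if X.isna().any().any():
        raise ValueError("membership covariates contain missing values; impute first")
    member = np.r_[np.zeros(len(dev)), np.ones(len(val))]
    flagged = False
    try:
        res = performance.fit_logistic(member, X.to_numpy(dtype=float))
        prob = np.asarray(res.predict())
        if np.max(np.abs(res.params)) > 1e3 or prob.min() < 1e-8 or prob.max() > 1 - 1e-8:
            flagged = True
    except Exception:
        # (quasi-)separation: fall back to a barely-regularized fit
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e4, max_iter=5000)
        clf.fit(X.to_numpy(dtype=float), member)
        prob = clf.predict_proba(X.to_numpy(dtype=float))[:, 1]
        flagged = True
    disc = performance.auc(prob, member)
    a, lo, hi = disc.auc, disc.ci_low, disc.ci_high
    if a < 0.5:  # orientation
        a, lo, hi = 1 - a, 1 - hi, 1 - lo
        lo, hi = max(0.5, lo), hi
    lo = min(max(lo, 0.0), a)
    return RelatednessResult(a, lo, hi, _verdict(a), separation_flag=flagged)


def compare_lp(
    dev_lp: Sequence[float],
    val_lp: Sequence[float],
    *,
    equal_var: bool = False,
    variance_test: str = "F",
) -> LPComparison:
    """Compare the linear-predictor distributions of the two cohorts.

    Means via a two-sample t-test (Welch by default, pooled-variance with
    ``equal_var=True``); spreads via the F variance-ratio test, or Levene's
    test with ``variance_test="levene"``. Two-sided p-values throughout.
    """
    a = np.asarray(dev_lp, dtype=float)
    b = np.asarray(val_lp, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two LP values per cohort")
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    if sd_a == 0 or sd_b == 0:
        raise ValueError("degenerate (constant) LP vector: variance test undefined")
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    if variance_test == "F":
        f = float(sd_a**2 / sd_b**2)
        dfa, dfb = len(a) - 1, len(b) - 1
        cdf = stats.f.cdf(f, dfa, dfb)
        p_var = float(2 * min(cdf, 1 - cdf))
        stat_var = f
    elif variance_test == "levene":
        lev = stats.levene(a, b)
        stat_var, p_var = float(lev.statistic), float(lev.pvalue)
    else:
        raise ValueError(f"unknown variance test {variance_test!r}")
    return LPComparison(
        mean_dev=float(a.mean()),
        mean_val=float(b.mean()),
        sd_dev=float(sd_a),
        sd_val=float(sd_b),
        t_statistic=float(t_res.statistic),
        t_pvalue=float(t_res.pvalue),
        variance_statistic=stat_var,
        variance_pvalue=min(1.0, p_var),
        variance_test=variance_test,
    )


def assess_relatedness(
    dev: pd.DataFrame,
    val: pd.DataFrame,
    model: LogisticPredictionModel,
    outcome_col: str = OUTCOME_COL,
) -> tuple[RelatednessResult, LPComparison]:
    """Full step-1 assessment: membership AUC and LP comparison."""
    covs = list(model.coefficients) + [outcome_col]
    rel = membership_auc(dev, val, covs)
    cmp_ = compare_lp(model.linear_predictor(dev), model.linear_predictor(val))
    return rel, cmp_
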