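"""Discrimination and calibration of probabilistic predictions.

Step 2 of the three-step external-validation framework: given predicted
event probabilities and observed binary outcomes, quantify

* discrimination — the concordance statistic (AUC) with a DeLong
  confidence interval, plus the conventional Hosmer-Lemeshow banding
  (acceptable / excellent / outstanding);
* calibration — the expected-to-observed (E:O) event ratio,
  calibration-in-the-large (CITL: the intercept of a logistic regression
  of outcomes on the logit of the predictions held as a fixed offset),
  and the calibration slope (the LP coefficient in a free-intercept
  logistic fit). E:O > 1, CITL < 0 and slope < 1 all signal
  overprediction / overfitting of the transported model;
* a grouped calibration curve (prediction deciles with binomial CIs,
  optionally a lowess smoother) for calibration plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.proportion import proportion_confint

from .model import clip_risk

__all__ = [
    "DiscriminationResult",
    "CalibrationResult",
    "CalibrationCurve",
    "auc",
    "auc_point",
    "classify_discrimination",
    "eo_ratio",
    "citl",
    "calibration_slope",
    "calibrate_metrics",
    "calibration_curve",
    "fit_logistic",
]

_Z95 = norm.ppf(0.975)


def _validate_pairs(predictions, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length 1-D arrays")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return p, y.astype(int)


# ---------------------------------------------------------------------------
# Logistic fitting (IRLS via statsmodels GLM, tight convergence)
# ---------------------------------------------------------------------------

def fit_logistic(
    y: np.ndarray,
    X: np.ndarray | None,
    offset: np.ndarray | None = None,
):
    """Binomial GLM fit used for CITL, slope, recalibration and membership
    models. ``X`` excludes the constant (added here); ``X=None`` fits an
    intercept-only model. Raises on non-convergence."""
    exog = (
        np.ones((len(y), 1))
        if X is None
        else sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    )
    model = sm.GLM(np.asarray(y, dtype=float), exog, family=sm.families.Binomial(),
                   offset=offset)
    res = model.fit(maxiter=200, tol=1e-10)
    if not res.converged:
        raise RuntimeError(
            f"logistic fit did not converge after {res.fit_history['iteration']} IRLS iterations"
        )
    return res


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminationResult:
    auc: float
    ci_low: float
    ci_high: float
    band: str
    n_events: int
    n_nonevents: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValueError("AUC CI must lie in [0,1] and bracket the estimate")


def auc_point(predictions, outcomes) -> float:
    """Concordance (rank) estimator of the AUC, ties counted half."""
    p, y = _validate_pairs(predictions, outcomes)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    from scipy.stats import rankdata

    r = rankdata(p)  # midranks handle ties as 1/2
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(p: np.ndarray, y: np.ndarray) -> float:
    """DeLong structural-component variance of the AUC estimate."""
    cases = p[y == 1]
    controls = p[y == 0]
    m, n = len(cases), len(controls)
    # placement of each case among controls and vice versa
    v10 = np.empty(m)
    v01 = np.empty(n)
    order = np.sort(controls)
    # P(control < case) + 0.5 P(control == case), vectorized via searchsorted
    lo = np.searchsorted(order, cases, side="left")
    hi = np.searchsorted(order, cases, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / n
    order_c = np.sort(cases)
    lo = np.searchsorted(order_c, controls, side="left")
    hi = np.searchsorted(order_c, controls, side="right")
    v01 = ((m - hi) + 0.5 * (hi - lo)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc(predictions, outcomes) -> DiscriminationResult:
    """AUC with a 95% DeLong confidence interval and Hosmer-style band."""
    p, y = _validate_pairs(predictions, outcomes)
    point = auc_point(p, y)
    se = float(np.sqrt(_delong_variance(p, y)))
    lo = min(point, max(0.0, point - _Z95 * se))
    hi = max(point, min(1.0, point + _Z95 * se))
    return DiscriminationResult(
        auc=point,
        ci_low=lo,
        ci_high=hi,
        band=classify_discrimination(point),
        n_events=int(y.sum()),
        n_nonevents=int(len(y) - y.sum()),
    )


def classify_discrimination(auc_value: float) -> str:
    """Hosmer banding: <0.70 poor, [0.70,0.80) acceptable, [0.80,0.90)
    excellent, >=0.90 outstanding."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc_value >= 0.90:
        return "outstanding"
    if auc_value >= 0.80:
        return "excellent"
    if auc_value >= 0.70:
        return "acceptable"
    return "poor"


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    eo: float
    eo_ci: tuple[float, float]
    citl: float
    citl_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    n_expected: float
    n_observed: int

    def __post_init__(self) -> None:
        # the E:O identity must hold exactly as reported
        if self.n_observed > 0 and abs(self.eo - self.n_expected / self.n_observed) > 1e-12:
            raise ValueError("E:O must equal expected/observed exactly")

    @property
    def interpretation(self) -> str:
        if self.eo > 1:
            return "overprediction"
        if self.eo < 1:
            return "underprediction"
        return "perfect agreement"


def eo_ratio(predictions, outcomes) -> float:
    """Sum of predicted risks over the number of observed events."""
    p, y = _validate_pairs(predictions, outcomes)
    o = int(y.sum())
    if o == 0:
        raise ValueError("no observed events; E:O undefined")
    return float(p.sum() / o)


def citl(predictions, outcomes) -> tuple[float, tuple[float, float]]:
    """Calibration-in-the-large: intercept of a logistic fit of the outcome
    with logit(prediction) as a fixed offset. 0 is ideal; negative means
    the predictions run systematically too high."""
    p, y = _validate_pairs(predictions, outcomes)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    res = fit_logistic(y, None, offset=logit(clip_risk(p)))
    a = float(res.params[0])
    se = float(res.bse[0])
    return a, (a - _Z95 * se, a + _Z95 * se)


def calibration_slope(predictions, outcomes) -> tuple[float, tuple[float, float]]:
    """Slope of a logistic fit of the outcome on logit(prediction) with a free
    intercept. 1 is ideal; < 1 indicates overfitting-like spread."""
    p, y = _validate_pairs(predictions, outcomes)
    lp = logit(clip_risk(p))
    if np.ptp(lp) == 0:
        raise ValueError("constant linear predictor: slope unidentifiable")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    res = fit_logistic(y, lp[:, None])
    b = float(res.params[1])
    se = float(res.bse[1])
    return b, (b - _Z95 * se, b + _Z95 * se)


def calibrate_metrics(predictions, outcomes) -> CalibrationResult:
    """E:O, CITL and calibration slope with 95% CIs, in one pass.

    The E:O confidence interval uses a log transform with the Poisson
    approximation var(log O) ~ 1/O; CITL and slope CIs are model-based.
    """
    p, y = _validate_pairs(predictions, outcomes)
    o = int(y.sum())
    e = float(p.sum())
    ratio = eo_ratio(p, y)
    se_log = 1.0 / np.sqrt(o)
    eo_ci = (float(ratio * np.exp(-_Z95 * se_log)), float(ratio * np.exp(_Z95 * se_log)))
    a, a_ci = citl(p, y)
    b, b_ci = calibration_slope(p, y)
    return CalibrationResult(
        eo=ratio, eo_ci=eo_ci, citl=a, citl_ci=a_ci, slope=b, slope_ci=b_ci,
        n_expected=e, n_observed=o,
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Grouped observed-vs-predicted points for a calibration plot."""

    predicted: np.ndarray
    observed: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    counts: np.ndarray
    method: str

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def calibration_curve(
    predictions, outcomes, method: str = "deciles", bins: int = 10, span: float = 0.75
) -> CalibrationCurve:
    """Observed event proportion against mean predicted risk.

    ``deciles``: equal-count prediction bins with Wilson binomial CIs.
    ``smoother``: lowess of the outcome on the prediction over a grid
    (span 0.75 by default); CIs are not computed for the smoother.
    """
    p, y = _validate_pairs(predictions, outcomes)
    if method == "deciles":
        if len(p) < 2 * bins:
            raise ValueError(f"need at least {2 * bins} records for {bins} bins")
        edges = np.quantile(p, np.linspace(0, 1, bins + 1))
        edges = np.unique(edges)
        if len(edges) < 3:
            raise ValueError("predictions too concentrated to form bins")
        idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
        pred, obs, lo, hi, cnt = [], [], [], [], []
        for b in range(len(edges) - 1):
            mask = idx == b
            k = int(mask.sum())
            if k == 0:
                continue
            events = int(y[mask].sum())
            ci = proportion_confint(events, k, alpha=0.05, method="wilson")
            pred.append(float(p[mask].mean()))
            obs.append(events / k)
            lo.append(float(ci[0]))
            hi.append(float(ci[1]))
            cnt.append(k)
        return CalibrationCurve(
            np.array(pred), np.array(obs), np.array(lo), np.array(hi),
            np.array(cnt), "deciles",
        )
    if method == "smoother":
        grid = lowess(y, p, frac=span, it=0, return_sorted=True)
        px, ox = grid[:, 0], np.clip(grid[:, 1], 0.0, 1.0)
        return CalibrationCurve(
            px, ox, np.full_like(px, np.nan), np.full_like(px, np.nan),
            np.ones(len(px), dtype=int), "smoother",
        )
    raise ValueError(f"unknown method {method!r}")
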