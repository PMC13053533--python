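"""Seeded synthetic admission cohorts with realistic case-mix structure.

The hospital data behind a temporal external validation are rarely
shareable, so this module generates admission-level cohorts that carry the
statistical structure such a validation exercises:

* marginal predictor distributions matching published cohort tables
  (normal for vitals and chemistry, log-normal for skewed labs such as
  blood urea nitrogen and creatinine, Bernoulli for binary items);
* a Gaussian copula tying predictors together with weak physiologic
  correlation;
* outcomes drawn from a logistic "truth" model, so the event prevalence
  and predictor-outcome gradients are controlled;
* a case-mix *shift* between a development-like and a validation-like
  cohort, expressed as a target offset and scale on the distribution of
  the scored model's linear predictor (LP);
* an optional miscalibrated outcome model (``logit p = alpha + beta * LP``)
  reproducing the transported-model pattern — calibration slope below 1,
  expected-to-observed ratio above 1;
* MCAR/MAR missingness injection with target per-variable rates.

Defaults emulate a COPD-exacerbation mortality validation: development
cohort of 923 admissions with ~10.9% in-hospital mortality and LP moments
(-2.84, 1.54); validation cohort of 938 admissions, ~11.2% mortality, LP
moments (-2.54, 1.75); serum albumin missing at random for 46.5% of
admissions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .model import LogisticPredictionModel, PredictorSpec, clip_risk

__all__ = [
    "Marginal",
    "CohortSpec",
    "ShiftSpec",
    "MissingnessSpec",
    "generate_cohort",
    "apply_shift",
    "inject_missingness",
    "induced_lp_moments",
    "calibrate_model_to_lp",
    "perturb_outcome_model",
    "solve_outcome_intercept",
    "development_spec",
    "validation_spec",
    "default_missingness",
    "lognormal_from_median_iqr",
]

_CAL_N = 200_000  # Monte-Carlo size used for internal spec calibration


@dataclass(frozen=True)
class Marginal:
    """Marginal distribution of one cohort variable.

    ``dist`` is ``"normal"`` (mean/sd on the natural scale), ``"lognormal"``
    (mean/sd are the location/scale of log(X)), or ``"binary"`` (``p`` is the
    success proportion; mean/sd ignored).
    """

    dist: str
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "lognormal", "binary"):
            raise ValueError(f"unknown marginal {self.dist!r}")
        if self.dist == "binary" and not 0.0 <= self.p <= 1.0:
            raise ValueError("binary proportion must lie in [0, 1]")
        if self.dist != "binary" and self.sd < 0:
            raise ValueError("marginal SD must be >= 0")

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal latent draws to this marginal."""
        if self.dist == "normal":
            return self.mean + self.sd * z
        if self.dist == "lognormal":
            return np.exp(self.mean + self.sd * z)
        return (z < norm.ppf(self.p)).astype(float) if 0 < self.p < 1 else np.full(
            z.shape, float(round(self.p))
        )


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> Marginal:
    """Log-normal marginal matching a published median and interquartile range."""
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2 * norm.ppf(0.75))
    return Marginal("lognormal", mu, sigma)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    Parameters
    ----------
    n
        Number of admissions.
    marginals
        Mapping variable name -> :class:`Marginal`; generation order follows
        this mapping.
    correlation
        Latent-scale correlation matrix aligned with ``list(marginals)``;
        must be symmetric PSD with unit diagonal. ``None`` means independence.
    truth_model
        The logistic model whose LP defines the case mix (the model under
        validation, or the data-generating truth when they coincide).
    outcome_model
        Model outcomes are actually drawn from; defaults to ``truth_model``.
        Supplying a perturbed model creates transported-model miscalibration.
    seed
        Master seed; all generation substreams derive from it.
    recurrence
        Expected fraction of unique patients among admissions (recurrent
        admissions share a patient id but are treated as independent records).
    """

    n: int
    marginals: Mapping[str, Marginal]
    truth_model: LogisticPredictionModel
    correlation: np.ndarray | None = None
    outcome_model: LogisticPredictionModel | None = None
    seed: int = 0
    recurrence: float = 0.71

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        object.__setattr__(self, "marginals", dict(self.marginals))
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            k = len(self.marginals)
            if r.shape != (k, k):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(r, r.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(r), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise ValueError("correlation matrix is not positive semi-definite")
            object.__setattr__(self, "correlation", r)
        missing = set(self.truth_model.coefficients) - set(self.marginals)
        if missing:
            raise ValueError(f"truth model predictors without marginals: {sorted(missing)}")

    @property
    def variables(self) -> list[str]:
        return list(self.marginals)

    def scoring_outcome_model(self) -> LogisticPredictionModel:
        return self.outcome_model if self.outcome_model is not None else self.truth_model


def _latent(spec: CohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    k = len(spec.marginals)
    z = rng.standard_normal((n, k))
    if spec.correlation is not None:
        # eigh-based square root tolerates exactly-singular PSD matrices
        w, v = np.linalg.eigh(spec.correlation)
        w = np.clip(w, 0.0, None)
        z = z @ (v * np.sqrt(w)) @ v.T
    return z


def _draw_predictors(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    z = _latent(spec, n, rng)
    cols = {
        name: m.transform(z[:, j]) for j, (name, m) in enumerate(spec.marginals.items())
    }
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort: predictors via the Gaussian copula, outcomes via the model.

    Returns a DataFrame with ``admission_id``, ``patient_id``, one column per
    spec variable, and a binary ``outcome`` column (1 = non-surviving
    admission). Identical specs (including seed) give identical cohorts.
    """
    rng = np.random.default_rng([spec.seed, 0x5EED])
    df = _draw_predictors(spec, spec.n, rng)
    risk = clip_risk(expit(spec.scoring_outcome_model().linear_predictor(df)))
    df["outcome"] = (rng.uniform(size=spec.n) < risk).astype(int)
    n_pat = max(1, int(round(spec.recurrence * spec.n)))
    df.insert(0, "patient_id", [f"P{j:06d}" for j in rng.integers(0, n_pat, spec.n)])
    df.insert(0, "admission_id", [f"A{j:06d}" for j in range(spec.n)])
    return df


def induced_lp_moments(
    spec: CohortSpec, n_mc: int = _CAL_N, stream: int = 1
) -> tuple[float, float]:
    """Monte-Carlo mean and SD of the truth-model LP under the spec."""
    rng = np.random.default_rng([spec.seed, 0xCA1, stream])
    df = _draw_predictors(spec, n_mc, rng)
    lp = spec.truth_model.linear_predictor(df)
    return float(np.mean(lp)), float(np.std(lp, ddof=1))


@dataclass(frozen=True)
class ShiftSpec:
    """Target change of the LP distribution: additive mean offset, SD scale."""

    lp_offset: float = 0.0
    lp_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.lp_sd_scale <= 0:
            raise ValueError("LP SD scale must be positive")


def apply_shift(spec: CohortSpec, shift: ShiftSpec) -> CohortSpec:
    """Return a spec whose induced LP distribution is offset and rescaled.

    The mean offset is distributed over the normal-marginal continuous
    predictors along the truth-model coefficient direction (the minimal
    translation in the standardized metric), which changes the LP mean by
    exactly ``lp_offset``. The SD scale is achieved by multiplying those
    predictors' SDs by a common factor solved numerically against the
    induced LP SD. Binary and log-normal marginals are left untouched.
    """
    b = spec.truth_model.coefficients
    shiftable = [
        name
        for name, m in spec.marginals.items()
        if m.dist == "normal" and b.get(name, 0.0) != 0.0 and m.sd > 0
    ]
    if not shiftable:
        raise ValueError("no normal-marginal predictors with nonzero coefficients to shift")

    denom = sum((b[v] * spec.marginals[v].sd) ** 2 for v in shiftable)
    new_marg = dict(spec.marginals)
    for v in shiftable:
        m = new_marg[v]
        delta = shift.lp_offset * b[v] * m.sd**2 / denom
        new_marg[v] = replace(m, mean=m.mean + delta)

    base_mean, base_sd = induced_lp_moments(spec)
    target_sd = shift.lp_sd_scale * base_sd

    def sd_at(kappa: float) -> float:
        marg = {
            v: (replace(new_marg[v], sd=kappa * new_marg[v].sd) if v in shiftable else new_marg[v])
            for v in new_marg
        }
        trial = replace(spec, marginals=marg)
        return induced_lp_moments(trial)[1]

    if abs(shift.lp_sd_scale - 1.0) < 1e-12:
        kappa = 1.0
    else:
        kappa = brentq(lambda k: sd_at(k) - target_sd, 1e-6, 50.0, xtol=1e-6)
    marg = {
        v: (replace(new_marg[v], sd=kappa * new_marg[v].sd) if v in shiftable else new_marg[v])
        for v in new_marg
    }
    return replace(spec, marginals=marg)


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-variable missingness targets under MCAR or MAR.

    Under MAR the probability of a value being missing depends only on the
    ``drivers`` — always-observed variables with log-odds weights per SD —
    with the intercept solved so the realized rate matches the target.
    """

    rates: Mapping[str, float]
    mechanism: str = "MCAR"
    drivers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be MCAR or MAR")
        for name, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {name!r} outside [0, 1]")
        if self.mechanism == "MAR" and not self.drivers:
            raise ValueError("MAR missingness requires driver variables")
        object.__setattr__(self, "rates", dict(self.rates))
        object.__setattr__(self, "drivers", dict(self.drivers))


def inject_missingness(
    records: pd.DataFrame, mspec: MissingnessSpec, seed: int
) -> pd.DataFrame:
    """Blank out values at the target rates; returns a copy with NaNs.

    MAR missingness probability is ``expit(a + sum_d w_d * standardized(d))``
    with ``a`` chosen per variable so the mean probability equals the target
    rate on this cohort. Driver variables must be fully observed.
    """
    df = records.copy()
    rng = np.random.default_rng([seed, 0x3117])
    if mspec.mechanism == "MAR":
        score = np.zeros(len(df))
        for d, w in mspec.drivers.items():
            col = pd.to_numeric(df[d], errors="coerce").to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(f"MAR driver {d!r} has missing values")
            s = col.std(ddof=0)
            score += w * ((col - col.mean()) / s if s > 0 else 0.0)
    for name, rate in mspec.rates.items():
        if rate == 0:
            continue
        if mspec.mechanism == "MCAR" or rate == 1:
            prob = np.full(len(df), rate)
        else:
            a = brentq(lambda a_: float(np.mean(expit(a_ + score))) - rate, -40, 40)
            prob = expit(a + score)
        mask = rng.uniform(size=len(df)) < prob
        df.loc[mask, name] = np.nan
    return df


# ---------------------------------------------------------------------------
# Model calibration helpers
# ---------------------------------------------------------------------------

def calibrate_model_to_lp(
    spec: CohortSpec, lp_mean: float, lp_sd: float
) -> LogisticPredictionModel:
    """Rescale a model's coefficients and intercept to hit target LP moments.

    Keeps the coefficient *direction* (the relative predictor effects) and
    solves the overall effect scale and intercept so the LP induced by the
    spec's marginals has the requested mean and SD.
    """
    rng = np.random.default_rng([spec.seed, 0xCA1, 2])
    df = _draw_predictors(spec, _CAL_N, rng)
    b = spec.truth_model.coefficients
    s = np.zeros(len(df))
    for name, coef in b.items():
        s += coef * df[name].to_numpy(dtype=float)
    kappa = lp_sd / float(np.std(s, ddof=1))
    coefs = {k: kappa * v for k, v in b.items()}
    intercept = lp_mean - kappa * float(np.mean(s))
    return replace(spec.truth_model, intercept=intercept, coefficients=coefs)


def perturb_outcome_model(
    model: LogisticPredictionModel, alpha: float, beta: float
) -> LogisticPredictionModel:
    """Outcome model with ``logit p = alpha + beta * LP_base``.

    Generating outcomes from this model while *scoring* with ``model``
    reproduces transported-model miscalibration: the calibration slope of the
    scored predictions converges to ``beta`` and systematic over/under-
    prediction is governed by ``alpha``.
    """
    return replace(
        model,
        intercept=alpha + beta * model.intercept,
        coefficients={k: beta * v for k, v in model.coefficients.items()},
        label=f"{model.label}|perturbed(a={alpha:.3g},b={beta:.3g})",
    )


def solve_outcome_intercept(
    spec: CohortSpec, beta: float, target_prevalence: float
) -> float:
    """Solve the ``alpha`` of a slope-``beta`` outcome perturbation so the
    cohort's expected event prevalence equals ``target_prevalence``."""
    rng = np.random.default_rng([spec.seed, 0xCA1, 3])
    df = _draw_predictors(spec, _CAL_N, rng)
    lp = spec.truth_model.linear_predictor(df)
    return float(
        brentq(
            lambda a: float(np.mean(expit(a + beta * lp))) - target_prevalence,
            -40,
            40,
        )
    )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Seven model predictors plus auxiliaries; marginals follow published
#: admission-cohort tables for hospitalized COPD exacerbations. The two
#: periods differ in individual marginals (consolidation prevalence, vitals
#: spread) beyond the LP-direction shift, which is what gives the membership
#: model its moderate discriminability.
def _default_marginals(period: str = "validation") -> dict[str, Marginal]:
    if period == "development":
        return {
            "mean_arterial_pressure": Marginal("normal", 97.4, 16.1),
            "age": Marginal("normal", 74.4, 11.0),
            "bun": lognormal_from_median_iqr(15.5, 11.0, 22.0),
            "intubation": Marginal("binary", p=0.712),
            "sodium": Marginal("normal", 138.7, 5.0),
            "body_temperature": Marginal("normal", 37.13, 0.65),
            "albumin": Marginal("normal", 3.84, 0.55),
            "male": Marginal("binary", p=0.86),
            "creatinine": lognormal_from_median_iqr(0.9, 0.8, 1.2),
            "consolidation": Marginal("binary", p=0.40),
            "fev1_fvc_ratio": Marginal("normal", 0.51, 0.10),
        }
    return {
        "mean_arterial_pressure": Marginal("normal", 102.8, 20.5),
        "age": Marginal("normal", 74.8, 11.3),
        "bun": lognormal_from_median_iqr(15.0, 11.0, 22.5),
        "intubation": Marginal("binary", p=0.728),
        "sodium": Marginal("normal", 138.6, 5.7),
        "body_temperature": Marginal("normal", 37.4, 1.0),
        "albumin": Marginal("normal", 3.73, 0.62),
        "male": Marginal("binary", p=0.86),
        "creatinine": lognormal_from_median_iqr(0.9, 0.7, 1.2),
        "consolidation": Marginal("binary", p=0.249),
        "fev1_fvc_ratio": Marginal("normal", 0.51, 0.10),
    }


def _default_correlation(names: Sequence[str]) -> np.ndarray:
    # weak positive coupling within the physiologic block; BUN-creatinine
    # strongly linked (both renal); otherwise independent
    physio = {
        "mean_arterial_pressure",
        "sodium",
        "body_temperature",
        "albumin",
        "bun",
        "creatinine",
    }
    k = len(names)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if names[i] in physio and names[j] in physio:
                r[i, j] = r[j, i] = 0.2
    i, j = names.index("bun"), names.index("creatinine")
    r[i, j] = r[j, i] = 0.6
    return r


def _direction_model() -> LogisticPredictionModel:
    """Plausible per-unit effect directions for the seven-predictor score;
    the overall scale is calibrated afterwards, so only ratios matter."""
    specs = (
        PredictorSpec("mean_arterial_pressure", "continuous", "mm Hg"),
        PredictorSpec("age", "continuous", "years"),
        PredictorSpec("bun", "continuous", "mg/dL"),
        PredictorSpec("intubation", "binary"),
        PredictorSpec("sodium", "continuous", "mmol/L"),
        PredictorSpec("body_temperature", "continuous", "degC"),
        PredictorSpec("albumin", "continuous", "g/dL"),
    )
    coefs = {
        "mean_arterial_pressure": -0.025,
        "age": 0.020,
        "bun": 0.025,
        "intubation": 1.20,
        "sodium": -0.015,
        "body_temperature": 0.15,
        "albumin": -1.10,
    }
    return LogisticPredictionModel(0.0, coefs, specs, label="synthetic-truth")


def development_spec(
    seed: int = 0,
    n: int = 923,
    lp_mean: float = -2.84,
    lp_sd: float = 1.54,
) -> CohortSpec:
    """Development-like cohort: 923 admissions, LP ~ (-2.84, 1.54), which
    yields ~10.9% in-hospital mortality under the logistic truth model."""
    marg = _default_marginals("development")
    corr = _default_correlation(list(marg))
    spec = CohortSpec(n, marg, _direction_model(), corr, seed=seed)
    truth = calibrate_model_to_lp(spec, lp_mean, lp_sd)
    return replace(spec, truth_model=truth)


def validation_spec(
    seed: int = 1,
    n: int = 938,
    lp_mean: float = -2.54,
    lp_sd: float = 1.75,
    outcome_slope: float = 0.536,
    prevalence: float = 0.112,
    dev: CohortSpec | None = None,
) -> CohortSpec:
    """Validation-like cohort: later-period marginals, case-mix shifted so
    the scored model's LP has moments (-2.54, 1.75), and scored-model
    miscalibration imposed (transported calibration slope ``outcome_slope``),
    with ~11.2% mortality.

    The truth model is inherited from the development spec, so scoring the
    validation cohort with it reproduces the overfitting pattern: slope < 1,
    E:O > 1, overprediction at high predicted risk.
    """
    base = dev if dev is not None else development_spec(seed=seed)
    spec = replace(base, n=n, seed=seed, marginals=_default_marginals("validation"))
    # residual shift along the coefficient direction lands the LP exactly on
    # the target moments despite the period-specific marginals
    m0, s0 = induced_lp_moments(spec)
    shifted = apply_shift(spec, ShiftSpec(lp_mean - m0, lp_sd / s0))
    alpha = solve_outcome_intercept(shifted, outcome_slope, prevalence)
    outcome = perturb_outcome_model(shifted.truth_model, alpha, outcome_slope)
    return replace(shifted, outcome_model=outcome)


def default_missingness(albumin_rate: float = 0.465) -> MissingnessSpec:
    """Serum albumin missing at random for 46.5% of admissions, driven by
    observed severity markers (intubation, outcome)."""
    return MissingnessSpec(
        rates={"albumin": albumin_rate},
        mechanism="MAR",
        drivers={"intubation": 0.8, "outcome": 0.5},
    )
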