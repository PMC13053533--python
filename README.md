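# extval — external validation of clinical logistic prediction models

`extval` is a Python library for *externally validating* a transported
clinical risk score — a fitted logistic model carried as frozen numbers into
a new time period or setting — against admission-level tabular data. It was
built around the temporal validation of a seven-predictor in-hospital
mortality score for hospitalized COPD exacerbations (mean arterial pressure,
age, blood urea nitrogen, endotracheal intubation, serum sodium, body
temperature, serum albumin), but every component is score-agnostic: any
intercept-plus-coefficients logistic model supplied as a YAML/JSON config can
be validated. The intended users are clinical epidemiologists and
biostatisticians running TRIPOD-style validation analyses.

## What it computes

For a score with linear predictor `LP = β₀ + Σ βⱼ xⱼ` and predicted risk
`p = expit(LP)`, the library implements the three-step validation framework:

1. **Relatedness.** A *membership model* — logistic regression of cohort
   membership (development vs validation) on the score's predictors and the
   outcome — whose apparent AUC measures case-mix separability (≈0.5 means
   exchangeable populations), plus a t-test / F variance-ratio comparison of
   the LP distributions.
2. **Performance.**
   - Discrimination: concordance statistic (AUC) by the midrank estimator,
     95% CI by DeLong's method, banded as poor / acceptable [0.70, 0.80) /
     excellent [0.80, 0.90) / outstanding ≥ 0.90.
   - Calibration: `E:O = Σ pᵢ / Σ yᵢ` (>1 ⇒ overprediction);
     calibration-in-the-large (CITL), the intercept `a` of
     `logit P(y=1) = a + offset(LP)` (0 ideal, negative ⇒ overprediction);
     calibration slope `b` in `logit P(y=1) = a + b·LP` (1 ideal, <1 ⇒
     overfitting); decile/lowess calibration curves.
3. **Updating.** Intercept recalibration (`α` with LP as offset),
   intercept+slope recalibration (`α + β·LP`), or full coefficient
   re-estimation, with a rule-based recommendation. On the fitting cohort the
   recalibrations satisfy the score-equation identities E:O = 1, CITL = 0
   (and slope = 1 for the joint update) exactly; neither changes the AUC.

Around this core: MICE imputation with predictive-mean-matching donors
(k = 10) and Rubin pooling for incomplete predictors; the C-statistic
precision criterion for minimum validation sample size; a seeded synthetic
cohort generator (Gaussian copula, case-mix shift on the LP scale, MCAR/MAR
missingness) standing in for the non-shareable hospital data; and report
assembly with deterministic content hashing.

## Worked example

`examples/` contains one narrative script per capability. Planning a
validation (`examples/01_plan_validation.py`):

```text
minimum validation sample size : 700 patients
expected outcome events        : 77
achieved 95% CI full width     : 0.1000
```

With an anticipated AUC of 0.82 and 11% outcome prevalence, 700 admissions
(77 deaths) keep the 95% CI of the validation AUC within a full width of
0.1. Running the full pipeline on the default synthetic cohorts
(`examples/03_assess_relatedness.py` … `05_update_model.py`):

```text
membership AUC: 0.67 (95% CI 0.64-0.69) -> related-but-different
LP mean dev vs val: -2.85 vs -2.46 (t = -5.13, p = 3.2e-07)
LP SD dev vs val:   1.52 vs 1.71 (F = 0.78, p = 0.00019)

pooled AUC  : 0.745 (95% CI 0.691-0.793)
pooled E:O  : 1.369 (95% CI 1.125-1.665)
pooled CITL : -0.475 (95% CI -0.716--0.234)
pooled slope: 0.574 (95% CI 0.418-0.729)

original               : E:O 1.418, CITL -0.523, slope 0.609
intercept update       : E:O 1.000, CITL -0.000, slope 0.609
intercept+slope update : E:O 1.000, CITL -0.000, slope 1.000
recommendation: intercept+slope
```

Reading: the validation period is distinguishable from development
(membership AUC 0.67) but overlapping; the transported score still ranks
patients acceptably (pooled AUC 0.745 across ten PMM-completed datasets) yet
systematically overpredicts (E:O > 1, CITL < 0) and is overfit (slope < 1).
Intercept updating fixes the average level; the joint update also restores
the slope; discrimination is unchanged by either.

The shipped `configs/example_model.yaml` is a synthetic, non-clinical
illustration of the config schema — real coefficient values must come from
the original score publication.

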