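# Methods

## Setting and model class

The package validates *transported* binary-outcome logistic scores: the model
is a frozen intercept plus named coefficients, the unit of observation is one
hospital admission, and recurrent admissions of the same patient are treated
as independent records. Predicted risks are clipped to
[1e−10, 1 − 1e−10] before any downstream logit, so recalibration and CITL
fits never see infinite offsets. Cohorts are plain tables (CSV in, empty cell
= missing); missingness is always an explicit NaN, never a sentinel value.

The eligibility filter drops admissions with age strictly below 40 years,
then admissions whose *observed* FEV1/FVC ratio is strictly above 0.7;
admissions without spirometry are retained (their COPD diagnosis rests on
discharge coding). The filter is idempotent and reports per-reason tallies.

## Step 1 — relatedness

The membership model regresses cohort membership on the score's predictors
plus the outcome and reports its *apparent* (in-sample) AUC — no
cross-validation, matching how the diagnostic is used in practice. The AUC is
orientation-normalized to ≥ 0.5, so it is invariant to swapping cohort
labels. Verdict thresholds (< 0.6 similar, 0.6–0.8 related-but-different,
> 0.8 different) are an interpretive convenience, labeled as such in the
result. (Quasi-)separation is flagged on the result — falling back to a
barely regularized fit for the probabilities — rather than raised.

LP distributions are compared with Welch's t-test by default (pooled-variance
optional) and an F variance-ratio test with two-sided p
(`2·min(cdf, 1−cdf)`); Levene's test is exposed as a robust alternative for
heavy-tailed LPs.

## Step 2 — performance

*Discrimination.* AUC by the midrank (concordance) estimator, ties counted
half; the 95% CI uses DeLong's structural-components variance with normal
quantiles, truncated to [0, 1]. The banding applies left-closed intervals, so
0.80 and 0.90 fall in the upper band. An independent O(n²) concordance count
and `sklearn.metrics.roc_auc_score` serve as cross-checks in the tests; the
estimator itself is implemented here.

*Calibration.* E:O is reported with a log-scale CI using the Poisson
approximation var(log O) ≈ 1/O. CITL and slope come from binomial GLM fits
(statsmodels IRLS, tolerance 1e−10, iteration cap 200) with model-based
standard errors. The calibration curve uses ten equal-count prediction bins
with Wilson binomial CIs, plus an optional lowess smoother (span 0.75, no
robustness iterations); the smoother choice is a package convention recorded
in the output, not a canonical definition.

## Step 3 — updating

Intercept recalibration fits `logit P = α + offset(LP)`; joint recalibration
fits `logit P = α + β·LP`. The maximum-likelihood score equations make
E:O = 1 and CITL = 0 (and slope = 1 for the joint update) *identities* on the
fitting cohort at convergence — the package asserts them to 1e−6 rather than
treating them as empirical findings. Re-estimation refits all coefficients,
flags separation, guards on a minimum of 10 events, and marks its in-sample
metrics as optimistic; no bootstrap optimism correction is attempted. The
updating recommendation is a documented rule table: CITL 95% CI excluding 0 →
intercept update; slope CI excluding 1 → intercept+slope; both plus poor
discrimination (AUC < 0.70) → consider re-estimation. These triggers are a
repo convention — in source studies updating is usually applied descriptively.

## Missing data

MICE with predictive-mean-matching donors: per cycle each incomplete variable
is regressed on all other chain variables (ordinary least squares for
continuous, ridge-free logistic for binary), predicted means are computed
with the same fitted coefficients for donors and recipients (type-0
matching — chosen so a given seed fully determines the imputation), and one
of the k = 10 nearest donors by |Δ predicted mean| is copied uniformly at
random; distance ties break by record order after a per-variable seeded
shuffle. Imputed values are therefore always members of the observed support.
The outcome is deliberately part of the chain, as is standard when imputed
data feed outcome models. Defaults m = 10 datasets × 10 cycles are
conventional MI practice and exposed in the spec. Type-0 matching omits the
parameter-draw step of fully Bayesian PMM, so between-imputation variance is
somewhat understated at small n; Rubin pooling uses the classic
(m−1)(1 + W/((1+1/m)B))² degrees of freedom without the Barnard–Rubin
small-sample correction. Validation metrics are computed per completed
dataset and pooled (AUC on the logit scale, E:O on the log scale, CITL/slope
untransformed), not computed once on a stacked dataset.

## Sample size

The C-statistic precision criterion uses the Newcombe-style approximation

    var(Ĉ) = C(1−C)[1 + (n/2−1)(1−C)/(2−C) + (n/2−1)·C/(1+C)] / (n²φ(1−φ))

and returns the smallest integer n whose anticipated 95% CI full width
2·1.96·√var is at most the target w, with events = ⌈φ·n⌉. The "error margin"
is interpreted as the *full* CI width; under that reading the worked design
(C = 0.82, φ = 0.11, w = 0.1) lands on n = 700 with 77 events, and the
bracket width(n) ≤ w < width(n−1) is verified numerically in the tests. Risk
bands put both boundaries (5% and 15%) in the intermediate band;
the convention is configurable.

## Synthetic cohort generator

The generator emulates the study conditions of a temporal validation whose
hospital data cannot be shared:

- **Marginals** follow published admission-table summaries: normal for
  vitals and chemistry, log-normal for skewed renal labs (matching the
  published median exactly and the quartile ratio q3/q1 — one scale
  parameter cannot also absorb the slight log-asymmetry of the printed IQR),
  Bernoulli for binary items. Development and validation periods get their
  own marginal sets, so the two cohorts differ in more directions than the
  score's coefficient vector — which is what gives the membership model its
  moderate (~0.65) discriminability.
- **Dependence** is a Gaussian copula: weak (0.2) latent correlation within
  the physiologic block, 0.6 between BUN and creatinine, independence
  elsewhere. Joint structure is not published; these are modeling choices.
- **Truth model**: a plausible per-unit coefficient direction (hypotension,
  age, uremia, intubation, hyponatremia, fever, hypoalbuminemia) whose scale
  and intercept are calibrated by Monte Carlo (200k draws, seed-derived
  substream) so the development LP has mean −2.84 and SD 1.54 — implying
  ~10.9% mortality; the validation case mix is shifted to LP (−2.54, 1.75).
- **Case-mix shift** is exact in the mean (distributed over normal-marginal
  predictors along the coefficient direction, minimal translation in the
  standardized metric) and numerically solved in the SD (a common multiplier
  on those predictors' SDs, Brent root-finding against Monte-Carlo LP SD).
  Binary and log-normal marginals are left untouched by the shift.
- **Transported-model miscalibration**: validation outcomes are drawn from
  `logit p = α + 0.536·LP` with α solved so the expected prevalence is
  11.2%; scoring with the unperturbed model then shows the overfitting
  signature (slope < 1, E:O > 1, overprediction above predicted risk 0.2).
- **Missingness**: MCAR or MAR with always-observed drivers entering a
  logistic missingness model standardized per driver, intercept solved per
  variable so the realized rate hits the target; the default blanks serum
  albumin for 46.5% of admissions driven by intubation and outcome.

All randomness flows from one master seed through named `SeedSequence`
substreams; identical specs generate byte-identical cohorts. Default sizes
mirror the motivating study (923 development / 938 validation admissions);
convergence checks in the tests use 50k–100k draws, and the acceptance script
uses a 1,000-admission cohort — sizes at which the Monte-Carlo error of every
asserted quantity is well below its tolerance.

### What the generator does not emulate

Real cohorts have non-Gaussian dependence (threshold effects, ICU triage
feedback), informative missingness beyond MAR, within-patient correlation of
recurrent admissions, measurement error, and predictor–outcome associations
that are not exactly logistic-linear. Passing tests therefore demonstrate
that the *estimators and procedures* behave correctly under a controlled,
realistic-scale data-generating process — not that any particular clinical
score is valid in any particular hospital.

## Known limitations

- The actual published coefficients of the motivating score are not shipped;
  the example config is synthetic and marked non-clinical.
- PMM type-0 matching and the absence of posterior draws make MI intervals
  mildly anti-conservative for small cohorts.
- E:O confidence intervals use the Poisson approximation, which ignores the
  (small) variability of Σp.
- No net-benefit/decision-curve analysis, no time-to-event handling, no
  penalized or Bayesian updating.
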