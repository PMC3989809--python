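# Methods

This note documents the statistical procedures, the defaults and the design
choices behind `rascore`, and what the synthetic-data experiments do and do
not demonstrate.

## Clinical definitions and derived variables

- **Outcome.** Significant renal artery stenosis: ≥50% lumen stenosis in at
  least one renal artery on angiography.
- **eGFR** is computed with the 4-variable IDMS-traceable MDRD equation,
  eGFR = 175 · Scr⁻¹·¹⁵⁴ · age⁻⁰·²⁰³ · (0.742 if female), in
  ml/min/1.73 m². The race factor is omitted because no race field is
  collected; the leading constant is exposed (`MDRD_CONSTANT`) for assays
  calibrated differently.
- **CKD stage ≥3** is eGFR < 60 (strict), per KDOQI convention.
- **Proteinuria** is a urine protein/creatinine ratio strictly above
  300 mg/g. A missing ratio is treated as "no proteinuria" and flagged
  (`upcr_missing`); rows missing any other modelling variable are excluded
  with a logged count.
- **Fixed clinical category.** Taking ≥4 anti-hypertensive medications is a
  pre-specified binary risk factor, not a Youden-derived cut
  (`AHM_RISK_COUNT`, configurable).

## Cut-point selection

Candidate thresholds are the **distinct observed values** of a covariate, so
any reported cut-off is attainable from the data; midpoint conventions would
report values that never occur. The Youden index is maximized in exact
integer arithmetic (J scaled by n₁·n₀) so ties are resolved
deterministically to the **smallest cut-off** in the risk direction. Risk
directions are fixed a priori (age ≥, CIMT ≥, cholesterol/HDL/triglyceride
≥, BMI <); when a direction is not supplied, the one giving AUC ≥ 0.5 is
chosen. The AUC p-value uses the continuity-corrected normal approximation
to the Mann–Whitney U statistic under the no-tie null; at n₁ = n₀ = 3 it
agrees with the exact permutation null to 0.01.

## Logistic fitting and backward elimination

The fitter is Fisher-scoring IRLS with step-halving. Convergence requires
max |X'(y−p̂)| < 1e−8 or a relative log-likelihood change < 1e−10, within 50
iterations; at every accepted solution the score equations hold to 1e−6, so
the fitted probabilities sum to the event count. Complete or quasi-complete
separation is declared when a non-intercept coefficient diverges past |β| =
15 while the score has not vanished, and is reported as an error **naming
the offending term**; backward-selection and bootstrap paths drop that term
with a log entry and continue (penalized fits would change the estimator;
a Firth-type option was deliberately not made the default).

Categorical covariates use reference (dummy) coding — plaque extent with
"none" as reference — and are tested and eliminated as whole blocks by
multi-df Wald statistics (β'Σ⁻¹β against χ² with block df). Elimination
removes the largest Wald p among terms with p ≥ 0.10, refitting after each
removal. Variance inflation factors are 1/(1−R²ₖ) from OLS of each design
column on the rest.

With eight extraneous candidate terms and an exit threshold of p ≥ 0.10,
roughly one false retention per cohort is the *expected behaviour of the
procedure itself* (≈ 0.9⁸ ≈ 25% of runs retain none), amplified slightly by
the optimism of testing Youden-derived indicators on the data that chose
them. Simulation at n = 641 reproduces exactly this: every generating term
retained in ≥85% of replicate cohorts, median one extraneous retention.

## Bootstrap internal validation

Optimism is estimated by re-running the **entire** development pipeline —
cut-point re-derivation, re-dichotomization, backward re-selection — on each
of m bootstrap resamples (size n, with replacement, all draws from one
seeded generator). Each resample model is scored twice: C_boot on its own
resample and C_orig on the original cohort; optimism = mean(C_boot −
C_orig) over convergent resamples and bias-corrected AUC = apparent −
optimism (the standard Harrell convention, which also matches the reference
arithmetic 0.898 − 0.023 = 0.875). Resamples in which the pipeline fails
are skipped and counted; >20% failures raises a validity warning. An
Efron-style 0.632 estimator (0.632·out-of-bag + 0.368·apparent) is available
behind `compute_632` for comparison but is not the default, because the
procedure being emulated is plain optimism correction. Covariates that
become constant in a resample are dropped for that resample with a log
entry.

Calibration curves use lowess — tricube-weighted local linear regression,
span 0.75 by default, robustness iterations disabled because the response is
binary — of the observed outcome on the predicted probability;
`mean_abs_error` and `q90_abs_error` summarize |smoothed observed −
predicted| over subjects.

## Scoring system

Points are round(βₖ/β_min) with half-away-from-zero rounding (no published
ratio falls on .5; the convention only matters for user-supplied models).
Deriving points requires all retained coefficients positive, i.e. indicators
coded in the risk direction. The maximum score counts only the largest level
of a mutually exclusive categorical group. Score→probability calibration
refits the one-predictor logistic model by maximum likelihood; grouped
tables are expanded to per-subject records, which has the identical
likelihood to a weighted fit.

Grouped-table evaluation computes the tie-corrected Mann–Whitney AUC
directly from counts (events beat the controls below their score plus half
the controls at it), with a Wald CI from placement-value (DeLong) variances.
The Hosmer–Lemeshow χ² uses the observed score values as groups (the shape
the data arrive in), df = groups − 2 by default with the adjustment exposed;
decile grouping is not used. PPV/NPV are reported both from raw counts and
prevalence-adjusted via Bayes' formulas when a prevalence is supplied —
the two differ at the fourth decimal on the reference table. The
goodness-of-fit R² between observed and predicted per-score frequencies is
from ordinary least squares; a nonlinear (Levenberg–Marquardt-style) target
could give slightly different values, so published R² figures are treated as
lower bounds in tests.

## Synthetic cohort generator

The generator defines the study conditions for every simulation-based test:
n = 641, target prevalence 0.094, and the published coefficients on the
published cut-offs (age ≥67 y, BMI <22 kg/m², CIMT ≥1.0 mm, CKD ≥3, ≥4
AHM, significant CAD, plaque extent). Covariate marginals follow the
published baseline table: normal age 61.2 ± 12.5 (truncated 18–100), BMI
25.4 ± 3.5, total cholesterol 175.8 ± 41.1; lognormal CIMT matched to
median 0.85 (0.73, 0.99) mm, HDL 46 (39, 55), triglyceride 121 (88, 172),
creatinine matched to mean 0.87 ± 0.37; binary prevalences male 0.49,
hypertension 0.61, diabetes 0.278, smoking 0.27, CAD 0.26; plaque extent
multinomial (0.58, 0.21, 0.21) so overall plaque prevalence is 42% (the
unilateral/bilateral split is not published and is configurable). The AHM
count is Poisson(1.6): the published SD of 1.0 implies mild underdispersion
that no standard count family reproduces without an arbitrary cap, so the
mean is matched and P(AHM ≥ 4) ≈ 0.079 follows. The urine
protein/creatinine ratio is lognormal (median 80 mg/g, σ = 1.22), giving
~14% proteinuria.

The intercept is solved by bisection on [−20, 20] so that the Monte-Carlo
mean of σ(α* + Σβx) over 200,000 sampled covariate vectors hits the target
prevalence (the mean probability is strictly increasing in α*, so bisection
is exact to the Monte-Carlo error, ±0.002).

Covariates are sampled **independently** by default — consistent with the
published mean VIF of 1.19 — with one structural exception: CKD stage
derives from sampled creatinine, age and sex through the MDRD equation, so
it correlates with the age indicator by construction. An optional Gaussian
copula imposes a correlation matrix on the continuous covariates for stress
tests. Because creatinine and age are otherwise independent, the derived
CKD ≥3 prevalence (~20%) exceeds the 7% of the real cohort; the intercept
solver compensates, and what the tests need is indicator variation, not the
real joint distribution. Emulating the real cohort beyond the stated
marginals and coefficients is explicitly out of scope — passing tests show
the *procedures* behave correctly under a known risk structure, not that
the published model generalizes.

## Problem sizes used in the test suite

Simulation scales were chosen to make Monte-Carlo conclusions stable:
parameter recovery uses 100 replicate cohorts of n = 50,000 (per-coefficient
recovery SDs 0.03–0.05 at 9.4% prevalence); the bootstrap-optimism envelope
uses 20 study-scale cohorts (n = 641) with m = 200 resamples each; the
optimism-shrinks-with-n check uses 10 seeds at m = 40 contrasting n = 641
with n = 5,000. All randomness flows from explicitly stated seeds;
re-running the suite is deterministic.

## Known limitations

- The score-only recalibration and the Hosmer–Lemeshow expected counts are
  computed from the same grouped table; the HL p-value therefore tests
  calibration-in-the-large of the logistic shape, not external validity.
- The grouped-AUC confidence interval is a symmetric Wald interval on the
  AUC scale; logit-scale or bootstrap intervals would be asymmetric near 1.
- Separation handling (drop-and-log) keeps the estimator faithful to the
  emulated procedure but discards information a penalized fit would retain.
- The generator matches marginals, not the joint distribution, of the real
  cohort; absolute coefficient values from synthetic fits are only
  comparable to the generating values, not to the published cohort's data.
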