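# Methods

This note records the modelling choices behind `circashift`: the assumptions
of each stage, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that the
results depend on.

## 1. Workload metrics

**Shift classification.** A worked interval is an EVENING shift if it
contains at least four consecutive worked hours inside [18:00, 24:00), and a
NIGHT shift if it contains at least four inside [00:00, 08:00). A long night
(18:00–08:00 with a three-hour nap) satisfies both rules; we give NIGHT
precedence, which is a convention — the source definitions do not say how a
shift qualifying for both windows is labelled. Net hours are gross duration
minus nap hours, with the nap deducted from the night window (where the nap
occurs in practice). Events longer than 24 h are rejected as malformed, and
an event is attributed to the four-week window its *start* falls in, so a
long night begun on the final window day still counts. Timestamps are naive
local time; DST is ignored (single-site, four-week windows).

**Work intensity.** Unit-level CMI is min–max normalised to a [0, 2]
severity scale per hospital (a fixed-range mode is available; a constant CMI
column maps to the midpoint 1.0 by convention). Expected NPR is
`a·exp(b·severity)` with (a, b) refit from the three anchor points by
least squares *on the original ratio scale*: for fixed b the optimal a is
the closed form `Σy·e^{bs} / Σe^{2bs}`, and the one-dimensional profile in b
is minimised numerically (bounded search on [−10, 10], tolerance 1e−12).
This is deliberately not the log-linear regression fit, which minimises a
different criterion; the test suite checks that the profiled fit dominates
it on the original scale. Workload over a window is the net-hours-weighted
mean of per-period expected/actual NPR ratios, so that exposure
(= workload × hours) is additive over periods. Nurses whose unit/period has
no census row get work-quantity indicators only; intensity fields are left
missing rather than imputed.

## 2. Preprocessing

Instrument scores are bounded, discrete and right-skewed. The recipe per
continuous variable is: (1) outlier fences at Q1 − 3·IQR / Q3 + 3·IQR —
3× rather than 1.5× because legitimate scores on a bounded skewed scale
easily exceed Tukey's inner fences; quartiles use the linear-interpolation
(type-7) convention, stated because the fences depend on it; (2) median
imputation (mode for categoricals), aborting if more than 20% of a column
would be imputed; (3) Yeo–Johnson transform with maximum-likelihood λ;
(4) z-scoring with the training mean/SD. The recipe is serialisable and is
the single mapping between raw scores and the standardized model scale —
model fitting, prediction, and simulation all go through it. New raw values
outside the training fences are winsorised to the fences (with the
understanding that simulation scenarios can push demand variables beyond
the observed range).

Univariate statistics are nonparametric throughout: tie-corrected Spearman
correlations with asymptotic p-values, Mann–Whitney U (two groups,
two-sided) and Kruskal–Wallis H (three or more).

## 3. Moderated GLMs

For each outcome (PSQI, PHQ-9) three candidate models share the main-effect
set — the partner symptom score, FR, LV, the three demand variables, and
confounders (age, gender, day workload exposure; BMI for the sleep model) —
and differ in which demand variable enters the interaction terms. The
source analysis never states the family/link; the published intercepts
(2.114 and 1.809) sit at the log of the outcome medians (8 and 7), so the
default is a Poisson log-link GLM on the raw integer score, with a Gaussian
(identity or log) alternative switchable. The outcome is *not*
Yeo–Johnson-transformed; predictors are. Interactions are products of the
standardized mains, computed after standardization, so all coefficients are
on a common standardized scale and the fit is invariant to the order of the
two factors in a product term.

Model ranking is by AIC, then BIC, then pseudo-R², then fewer parameters.
Pseudo-R² defaults to 1 − deviance/null-deviance (McFadden available); the
source does not define its version, which is one reason published fit
statistics are treated as generator truths rather than fit targets.
VIF is computed from auxiliary OLS regressions with intercept; values
beyond 1e6 (duplicated columns) are reported as infinite. IRLS runs to a
deviance tolerance of 1e−8 with at most 100 iterations; non-convergence is
an error, not a warning.

## 4. Nonlinear screen and breakpoint

The GAM uses cubic B-spline bases (default 10 basis functions per smooth,
shrunk to n_distinct − 1 for discrete demand variables; below five distinct
levels a smooth is refused) with smoothing parameters selected by GCV.
A term is flagged nonlinear when its effective degrees of freedom (trace of
the term's smoother sub-matrix) exceed 1.2 *and* its smooth is significant
at 0.05. The 1.2 threshold operationalises "substantially above 1"; the
linear limit (penalty → ∞ ⇒ EDoF → 1) is verified numerically in the tests.
The Gaussian-identity family is the default for the screen, matching the
scale on which the published GCV/variance-explained figures are coherent.

The breakpoint model is the continuous hinge `y = b0 + b1·x + b2·(x−c)+`,
fitted by OLS at every candidate c and minimised over an exhaustive grid —
by default every distinct observed x between the 5th and 95th percentiles
with at least 10 observations strictly on each side. Continuity at the
breakpoint holds by construction (this is why the hinge, not disjoint
per-segment OLS, is the default; the latter is what a discontinuous fit
would need and is intentionally not offered as a default). Segment slopes
are b1 (below) and b1 + b2 (above), with Wald p-values from the OLS
covariance (the above-slope variance includes the 2·cov term). The
slope-contrast (structural change) test is the Wald test on b2; its nominal
level applies at a fixed candidate — searching the grid first adds a
selection effect, so the type-I simulation in the tests evaluates the test
at the true breakpoint.

## 5. Trajectory simulation

Predictive functions invert the recipe: raw covariates → winsorise to
fences → Yeo–Johnson(λ) → z-score → linear predictor (with the same
standardized-product interactions as fitting) → inverse link → clip to the
instrument range. The coupled daily system updates synchronously: both
day-t predictions are computed from the day-(t−1) smoothed states before
either state advances, making the result independent of equation order.
The smoothing recursion is `s_t = α·pred + (1−α)·s_{t−1}` with α = 0.2
(20% current, 80% previous); with a constant prediction P it has the closed
form `P + (s0 − P)(1 − α)^t`, which the engine reproduces to 1e−12 and
which gives analytic threshold-crossing days used as test oracles.

Defaults: 100-day horizon; initial states PSQI = 1, PHQ-9 = 0 (the minimum
observed values — a low-symptom baseline); 1,000 bootstrap individuals;
noise off (trajectories are mean-field; optional per-day Gaussian
prediction noise exists for band realism). Thresholds: insomnia when mean
PSQI > 7, probable depression when mean PHQ-9 ≥ 10; crossings are read off
the group *mean* trajectory, with the per-individual crossing fraction
reported alongside because the two can differ substantially. Bands are
across-individual SDs, not Monte-Carlo SEs.

Scenario runs classify adaptability from cohort FR/LV quartiles — moderate
(both scores inside the interquartile band), high (FR ≥ P75 and LV ≤ P25),
low (FR ≤ P25 and LV ≥ P75), everything else unclassified — and apply a
demand multiplier jointly to the bundle (night count, shift hours, shift
workload exposure: baseline 4 / 44 / 147 ratio·hours), since the scenario
axis of interest is overall demand, not one component.

## 6. Synthetic cohorts

The generator emulates the published *cross-sectional* structure:

* **Marginals** are beta distributions scaled to each instrument's observed
  range and discretized by rounding, with (α, β) solved numerically from
  two published targets per variable. For most variables these are the
  median and IQR (the continuous 0.5-quantile is placed at the reported
  median). For PSQI and PHQ-9 a screening prevalence is also published,
  which pins the CDF at the cutoff half-integer (7.5 and 9.5) more sharply
  than the median does; those two marginals are therefore solved from
  {prevalence CDF point, IQR}, which reproduces the reported median, IQR
  and prevalence simultaneously. Gender is Bernoulli (89.58% female), age
  uniform-discrete on 24–44. Demand-variable marginals (night count median
  4, shift hours median 44, exposure median 147) use ranges a four-week
  roster can produce; BMI and the exposures stay continuous.
* **Dependence** is a Gaussian copula targeting the published Spearman
  correlations via the exact bivariate-normal identity r = 2·sin(πρ/6).
  Only significant pairs are published, so unspecified cells default to 0 —
  including mechanically coupled demand pairs; this is a stated modelling
  choice, flagged in provenance. The latent matrix is repaired to the
  nearest PSD matrix by eigenvalue clipping; if the repair moves a
  *specified* pair's ρ by more than 0.1 the configuration is rejected with
  the offending pairs named.
* **Model mode** plants a known GLM: covariates (including a copula-drawn
  partner score) come from the copula, the outcome is drawn from the
  declared family with the published standardized coefficients as truth,
  then clipped and rounded to the instrument grid. Generating the moderator
  conditionally on a copula version of the other score avoids the circular
  PSQI↔PHQ-9 definition while preserving each model's recovery test.
* **Piecewise mode** plants the published dose-response: breakpoint 24 h per
  four weeks, slopes −0.221 / +0.031 PSQI per hour, x uniform on [0, 80] h
  (≥ 20% of mass on each side of the kink), intercept 9 PSQI points and
  Gaussian score noise SD 2 — the intercept keeps the mean curve well
  inside the instrument range so clipping is negligible, and SD 2 is a
  realistic residual scale for PSQI totals. Outcomes are rounded to integer
  scores by default; the exact noiseless-recovery oracle requires the
  un-discretized variant, available behind a flag.
* **Shift logs** place each week's shifts on distinct roster days: the
  day–night default is one long night plus four 8-h day shifts per week;
  evening mixes are configurable. A matching unit census (active nurses,
  assigned patients, CMI per unit-week) makes intensity metrics computable.

What the generator does **not** emulate: item-level questionnaire structure,
within-person day-to-day symptom dynamics (the simulator derives trajectories
from cross-sectional fits, not from longitudinal data), the full empirical
correlation matrix (unpublished), department-level clustering, or
measurement error in the workload records. A green calibration test
therefore establishes that the *estimators* recover the stated structure —
not that the stated structure is the true data-generating process of any
real cohort.

Note on the dose-response attribution: the below-breakpoint slope −0.221 is
described in the source once as a depression association and once (in the
figure) as a sleep-quality association; this package follows the
sleep-quality reading and plants both slopes on the PSQI outcome.

## 7. Reproducibility

Every generator and simulation takes an explicit integer seed; identical
(config, seed) gives byte-identical CSV artifacts, and per-scenario streams
are derived with `SeedSequence` spawn keys so results do not depend on
evaluation order. Every artifact carries a provenance record (config, seed,
planted truths, correlation repairs).

## 8. Known limitations

* Published fit statistics (AIC 1377.37, pseudo-R² 0.4403, the Table of
  fitted coefficients as *estimates*) cannot be reproduced without the
  original data; they function here as generator truths for recovery tests.
* The Poisson default treats bounded sum-scores as counts; overdispersion
  is not modelled (a robust-covariance option exists, and the Gaussian
  alternative is one config switch away).
* The breakpoint search is single-kink; multi-breakpoint and Bayesian
  change-point formulations are out of scope.
* Percentile-based adaptability groups are cohort-relative, so group
  membership shifts with the cohort's FR/LV distribution.
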