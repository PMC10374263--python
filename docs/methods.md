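# Methods notes

This note records the modeling choices, defaults and limitations of the
package, in the order of the analysis chain.

## Index construction

**Allostatic load.** The index is the classical additive count: each of
27 biomarkers contributes 1 when its value falls in the high-risk
quartile region, giving a 0–27 range. All threshold inequalities are
inclusive (≥ for upper rules, ≤ for lower rules; DHEA-S and urine
cortisol are two-sided, the four heart-rate-variability measures and HDL
are lower-tailed, all others upper-tailed). The default configuration
uses the published quartile constants so scores are reproducible without
a biomarker sample; `derive_cutpoints(..., "sample_quartile")` instead
takes the empirical 25th/75th percentile per biomarker (linear
interpolation, the numpy default) with the same risk directions, which
requires at least 8 non-missing values per biomarker. Missing biomarkers
raise an error by default; an explicit `missing="available"` policy
counts flags over the non-missing subset and records the denominator
(`n_scored`), since no standard convention exists for partial panels.
The additive count weighs every biomarker equally; latent-profile
alternatives are out of scope.

**Cumulative SED.** Items are coded 0 (none), 1 (mild/moderate), 2
(severe). Childhood has four items — father's education, mother's
education, welfare receipt (binary, 0 or 2) and father's occupation — so
the period range 0–8; parental education enters as two items because the
printed childhood range is only attainable that way. Adult waves have
six items (range 0–12); the life-course total spans 0–32. Standardized
scores divide by the item count (0–2 scale), making periods with
different item counts comparable; a square-root transform is available
to reduce right skew.

**Chronic pain.** The interference index is the mean of the five 0–10
items, computed first and categorized after (low ≤ 4 < high); the
boundary 4.0 is low-interference. Widespreadness counts the nine listed
sites; a respondent reporting chronic pain with no flagged listed site
is counted literally as 0 sites (category "0–2"), since pain at an
unlisted location is possible.

## Trajectory model

The growth mixture is fitted on standardized period scores with time
coded 0, 1, 2 (childhood, first wave, second wave); nothing in the data
identifies the spacing, so unit spacing is the documented convention.
Class membership is covariate-free multinomial. Random effects (none,
intercept, slope, or both) have a single shared variance per effect
across classes with diagonal covariance — the smallest identifiable
choice. The free-parameter count is 2K fixed effects + (K−1) weights +
1 residual variance + the random-effect variances; this rule is exposed
so users can reconcile criterion values across software, whose counting
conventions differ.

EM starts from jittered k-means on per-respondent OLS (intercept, slope)
pairs, with 10 seeded starts by default and the best final
log-likelihood kept. The M-step updates class means by weighted GLS and
the variance components by a bounded Nelder-Mead minimization of the
expected complete-data deviance with means profiled out (a generalized
EM step: accepted only when it improves, so the log-likelihood is
monotone — asserted every iteration). Convergence is a log-likelihood
change below `tol` (1e-6). A class share collapsing below 1/(2n) or a
degenerate residual variance triggers a fresh restart (up to 5), after
which the fit is flagged non-converged. Classes are relabeled by
descending baseline (t = 0) fitted mean so labels are reproducible;
modal assignment breaks posterior ties toward the lowest class index.

SABIC uses effective sample size (n+2)/24, verified against the
published one-class model-fit row (AIC 7315.50 / BIC 7341.81 / SABIC
7322.76 from ℓ = −3651.75, 6 parameters, n = 593). Relative entropy is
1 − Σ(−τ ln τ)/(n ln K), clipped to [0, 1], and 1 by convention for one
class. Selection discards fits with any class share below 5%, then
ranks by BIC, AIC, SABIC and entropy; if nothing survives the share
screen the best-BIC fit is returned carrying a warning flag.

## Regression

Multinomial fits use maximum likelihood (statsmodels MNLogit, Newton)
with the no-pain category as reference; negative-binomial fits use the
NB2 (quadratic mean-variance) parameterization with estimated
dispersion, the mainstream default. Intervals are Wald on the
coefficient scale, exponentiated for reporting; continuous confounders
enter uncentered; categorical confounders are one-hot coded against the
first sorted level. Extreme coefficients (|β| > 30) are treated as
evidence of separation and reported as errors rather than returned.

## Missing data

Little's test estimates the grand mean and covariance by EM under
multivariate normality and sums pattern-wise Mahalanobis distances of
observed-variable means; df = Σ p_j − p, complete data give d² = 0 with
p = 1 by convention. Near-singular pattern covariances are
ridge-regularized. The test applies to numeric-coded variables;
categorical confounders would enter as dummies, an approximation.

Imputation is fully conditional specification with 10 cycles per chain
(the literature's usual 5–20 range) and m = 20 chains by default to
mirror standard practice; chain c is seeded `seed + c`. Draw models:
linear regression plus Gaussian residual noise (continuous), logistic
(binary), multinomial logistic (categorical), Poisson regression
(count). This is a draw from the conditional model at the point
estimates, not a fully Bayesian draw of the parameters, which slightly
understates between-imputation variance at small n — a documented
simplification. Observed cells are never modified.

Rubin pooling uses T = W̄ + (1+1/m)B and the classical df
(m−1)(1 + W̄/((1+1/m)B))²; with B = 0 the interval reduces exactly to
the single-dataset normal interval.

## Mediation

The estimator fits M ~ X + C by OLS and Y ~ X + M + C by logistic
regression (Y a binary category dummy; each pain category is contrasted
against no pain). Counterfactual mediator values are simulated from the
fitted mediator model *including residual noise* — with a nonlinear
outcome link, plugging in conditional means is biased. Effects average
predicted outcome probabilities over the sample, over `n_sims` (10)
mediator draws, and over the two treatment-arm versions (arm-specific
values are also reported). The default contrast for a continuous
exposure is sample mean to mean + 1 SD; for a class exposure, a 0/1
dummy. Bootstrap (500 resamples by default) refits both models per
resample; intervals are percentile and the p-value is
2·min(frac ≤ 0, frac ≥ 0). With `n_boot=1` only point estimates are
returned. The proportion mediated is ACME/total and flagged unstable
when the total effect is within 1e-10 of zero.

Moderated mediation adds the moderator to both models and the
moderator × mediator product to the outcome model, then evaluates all
effects with the moderator fixed at requested levels (default mean and
mean ± 1 SD). Because the moderated fit re-estimates all coefficients,
its effects at a given level agree with the unmoderated analysis only in
expectation, not identically; the test suite checks this agreement under
a zero true interaction at simulation tolerance. Pooling across
imputations treats each effect's bootstrap variance as the
within-imputation variance and recomputes the proportion mediated from
the pooled ACME and total effect.

Sequential ignorability is an assumption, not a testable property; the
suite verifies only its plumbing counterpart (confounders independent of
everything leave the ACME unchanged).

## Synthetic cohort

The generator encodes the study conditions: class shares (0.457, 0.368,
0.175) for high-to-low, stable-low and medium-to-high trajectories;
standardized SED endpoints (1.4→0.5), (0.4→0.4), (0.8→1.5) chosen to
mimic the qualitative published shapes; within-class SD 0.2 on the 0–2
scale (enough overlap to be nontrivial, enough separation for a 3-class
solution to be recoverable at n ≈ 600). Period scores are decomposed
into valid item codes whose sum equals the rounded raw score exactly
(welfare only 0/2), so index scoring round-trips.

AL is drawn NB2 (gamma-Poisson) with log-mean = ln(5.25) + ln(1.02) ×
total SED and dispersion α = 0.2, capped at the structural maximum 27;
the baseline 5.25 calibrates the default cohort's mean AL to about 6.7.
In biomarker mode the drawn count is realized by placing exactly that
many biomarkers inside their risk regions (uniform draws within region),
so `score_al` reproduces the stored count row by row. Pain is drawn from
a three-category multinomial logit for interference (effects ln 1.15 per
recent-wave SED unit and ln 3.22 for the worsening class on the high
category) and, conditionally on pain, a logit for 3+ sites (ln 3.06
worsening class, ln 1.19 per AL unit, ln 1.69 per childhood SED unit,
ln 0.95 interaction); intercepts −0.97/−2.46/−2.55 calibrate the
category mix to roughly 64/24/12% and 37% widespread among painful.
Interference items are drawn uniformly with rejection into the band
implied by the category; site counts uniformly in {3..9} or weighted in
{0, 1, 2}. Confounders are five independent standard normals with zero
effects by default (hooks exist for nonzero confounding scenarios).
Missingness is MCAR cell blanking.

What the generator does **not** emulate: realistic marginal biomarker
distributions and their correlations, MAR/MNAR mechanisms, survey
weights, attrition, or measurement error in retrospective childhood
items. Passing tests therefore demonstrate the correctness of the
estimators under the assumed data-generating structure, not robustness
to real-data violations of it.

## Pipeline

Stages write plain-text outputs and downstream stages always re-read
those files, so cached and cold runs are byte-identical; the cache key
hashes the configuration, the input file and the package version.
Trajectory modeling runs on the complete SED data (imputation targets
confounders only, matching a design where core variables are
complete-case). Per-imputation regressions and mediation are pooled by
Rubin's rules. Default problem sizes in the examples and tests (cohorts
of 350–5,000, m = 2–5 imputations, 25–200 bootstrap resamples, K ≤ 3
grids) are chosen so a full run completes in seconds to a few minutes on
one core while keeping Monte-Carlo error well inside the asserted
tolerances; all are configurable upward.
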