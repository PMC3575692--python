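# Methods

## Problem and model

`markergain` studies how the apparent predictive performance of a logistic
regression model changes when a single novel risk factor (a "marker") is
added to it. Outcomes are binary; the generating model is

    logit(p_i) = β0 + β_c · x_c,i + β_rf · x_rf,i [+ β_b · x_b,i]

with intercept β0 = −1 by default, a continuous base covariate
x_c ~ N(0, σ_c²), and a marker x_rf that is either binary
(prevalence p_binary) or standard normal. The optional x_b ~ Bernoulli(0.5)
produces a two-covariate base model. Effect sizes are parameterized as odds
ratios, β = ln(OR).

Five measures are computed for the base model (without the marker) and the
extended model (with it), always in-sample on the fitting data (apparent
performance; no split or optimism correction):

- **c-statistic** — concordance probability / AUC. Computed by midranks
  (Mann–Whitney), so tied predictions count 1/2 per pair. This matches the
  rank-statistic definition; implementations that break ties differently
  may differ in the last digits on heavily tied data.
- **Brier score** — mean((p̂ − Y)²).
- **Scaled Brier score** — 1 − Brier/Brier_max with
  Brier_max = m(1−m)² + (1−m)m², m = mean(p̂). For any logistic fit with an
  intercept, m equals the observed event rate (score equation), so the two
  candidate readings of "mean outcome probability" coincide; we evaluate at
  the mean prediction so the identity holds for externally supplied
  probabilities too.
- **Nagelkerke R²** — Cox–Snell R² = 1 − exp(−LR/n) rescaled by its maximum
  1 − exp(2·ll₀/n), with LR the likelihood-ratio statistic against the
  intercept-only model.
- **Discrimination slope** — mean(p̂ | Y=1) − mean(p̂ | Y=0). Its change
  between the extended and base model is the IDI, and the package represents
  it as exactly that difference.

## Fitting

Logistic models are fitted by damped Newton–Raphson (equivalent to IRLS):
gradient tolerance 1e-8 (infinity norm), at most 100 iterations,
step-halving whenever a step would decrease the log-likelihood, and the
intercept initialized at logit(ȳ). Complete or quasi-complete separation
drives coefficients toward infinity while the gradient vanishes
numerically; a fit whose linear predictor saturates (|η| > 23, i.e. fitted
probabilities within ~1e-10 of 0 or 1) is therefore marked non-converged
instead of returning diverging coefficients. The fitter is cross-checked
against `statsmodels.Logit` in the test suite.

## Simulation design

Seven scenario families form full factorial grids over
exp(β_c) ∈ {1.00, 1.25, …, 4.00} (13), σ_c ∈ {0.25, …, 4.00} (16),
exp(β_rf) ∈ {1.25, 1.5, 2, 3, 5} (5), and, for binary markers,
p_binary ∈ {0.1, 0.25, 0.5} (3): 3120 binary-marker or 1040
continuous-marker scenarios per family. The families are the independent
binary and continuous marker; each of those with marker–covariate
correlation 0.5 or 0.8; and a two-covariate base model with an independent
binary marker. Each scenario defaults to 1000 replicates of 1000 subjects;
per-scenario results are means of per-replicate quantities (for these
linear aggregations this equals the difference of means, but the mean of
per-replicate differences is fixed as the contract).

Correlated markers are generated from a latent bivariate normal with SDs
(σ_c, 1) and correlation ρ; binary markers are obtained by thresholding the
unit-variance latent at the theoretical normal quantile Φ⁻¹(1 − p_binary),
which keeps the prevalence a population parameter (rather than forcing each
sample's empirical prevalence) and the replicates independent.

In the two-covariate family, the odds ratio of the Bernoulli base covariate
is half the continuous covariate's odds ratio, read literally as
exp(β_b) = exp(β_c)/2 (so exp(β_c) = 1 gives a protective β_b = ln 0.5); a
`two_covariate_rule="half_beta"` switch selects the alternative reading
β_b = β_c/2, since the intent is ambiguous when exp(β_c) < 2.

### Random numbers and common-random-number pairing

Every replicate draws from a `numpy` Generator keyed by (master seed, CRC of
the (exp(β_c), σ_c) cell, replicate index, redraw attempt), so runs are
bit-reproducible and scenarios can be executed in any order or in parallel
without stream collisions. The key deliberately excludes the marker odds
ratio, the prevalence, and the correlation, and the covariates are built
from two shared standard-normal vectors (x_c = σ_c·a,
z = ρ·a + √(1−ρ²)·b): matched scenarios across those factors therefore
share common random numbers. This is unbiased for every per-scenario mean
and sharply reduces the Monte Carlo variance of precisely the contrasts the
package reports (monotonicity in marker strength and prevalence,
attenuation across correlation levels).

### Non-convergence policy

A replicate whose base or extended fit fails to converge, or whose outcome
vector is degenerate (all 0 or all 1 — possible at small event counts), is
redrawn with a fresh sub-seed up to 5 attempts and counted in
`n_nonconverged`; a scenario with more than 10% unusable replicates after
redraws raises an error flagging it as pathological. This keeps each
scenario at its full replicate count without silently aggregating garbage
fits.

## Exploration of the results grid

`ImprovementAnova` regresses the per-scenario mean improvement in one
measure on the measure's own baseline value (continuous, 1 df), prevalence
(categorical, 2 df) and marker odds ratio (categorical, 4 df), plus all
two-way interactions — 22 coefficients, fitted by OLS with treatment coding
(reference levels p = 0.1, OR = 1.25). Predictions — the reported
quantity — are invariant to the coding. The model then predicts the
improvement for all 15 (prevalence, OR) cells at the median baseline
accuracy of the supplied grid. `summarize_relationship` reports, per
(OR, prevalence, correlation) stratum, the Spearman and Pearson
correlations between baseline value and improvement plus binned means; the
interactions of the baseline with both factors are included among the
two-way interactions.

## What the synthetic data do and do not emulate

The generator reproduces the study conditions exactly: Gaussian base
covariate, Bernoulli or Gaussian marker, logistic outcome, the factorial
grids above, 1000 × 1000 default sampling. It does not emulate features of
real clinical data — non-Gaussian or skewed covariates, measurement error,
missingness, more than one marker, calibration drift between cohorts, or
censored outcomes. Passing tests therefore establish the behaviour of the
performance measures under a correctly specified logistic model, not their
behaviour under model misspecification.

## Problem sizes used by tests and the acceptance script

The full design (3120 scenarios × 1000 replicates × 2 fits per family) is
supported by `run_family` with per-scenario streaming to CSV. The bundled
property suite and the acceptance script run a reduced grid chosen to
preserve every qualitative contrast: exp(β_c) ∈ {1, 2, 4},
σ_c ∈ {0.5, 2}, all five marker odds ratios, all three prevalences, 200
replicates of 1000 subjects (90 scenarios for the independent binary
family; the matched correlated runs restrict to OR ≥ 2, where attenuation
is a real effect). Closed-form anchors use single cohorts of 10⁵–10⁶
subjects.

On this reduced grid the qualitative findings asserted by the tests are:
improvement in every measure is non-decreasing in the marker odds ratio,
and in prevalence for OR ≥ 2; within each (OR, prevalence) stratum the
improvement is negatively rank-correlated with the baseline value of the
measure; mean improvement decreases as marker–covariate correlation rises
from 0 to 0.5 to 0.8 (cell-by-cell for 0.8 vs 0.5; in aggregate against
ρ = 0, because cells with exp(β_c) = 1 carry no attenuation signal — with
an uninformative base covariate the marker's marginal information is the
same at every ρ); and the prevalence spread of the ANOVA-predicted
improvement at OR = 5 exceeds the spread at OR = 1.25.

## Numerical choices and degenerate inputs

- c-statistic, discrimination slope and Nagelkerke R² require both classes
  present and raise an explicit error otherwise.
- The scaled Brier score raises a division-by-zero error when the mean
  predicted probability is 0 or 1.
- `nagelkerke_r2` clips likelihood-ratio statistics within −1e-8·|ll₀| of 0
  to 0 (round-off from two separately converged fits) and raises beyond
  that, signalling a failed fit.
- A constant marker column in the case-study workflow is dropped with a
  warning and yields all-zero changes rather than a singular design.
- Relative changes in the case-study report are delta/baseline, except the
  Brier score where the sign is flipped so an improvement (a decrease) is
  reported as a positive percentage.
- Missing data in the case-study workflow are handled complete-case, with
  the dropped-row count logged.

## Known limitations

- Apparent (in-sample) performance only; no optimism correction, so small
  positive gains appear even for a truly null marker.
- No standard errors or confidence intervals for scenario means or metric
  changes; the simulation reports means only.
- No reclassification or decision-analytic measures (NRI, decision curves)
  and no survival-outcome extensions.
- Parallelism is limited to what the deterministic per-replicate seeding
  enables; the package itself runs scenarios serially.
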