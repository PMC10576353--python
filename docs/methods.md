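# Methods

`epimr` implements the complete inference chain of a circulating-biomarker
study of cancer risk that combines a prospective nested case-control
analysis with a two-sample Mendelian randomization (MR) study: summary-
statistic MR estimators with instrument diagnostics, Bayesian enumeration
colocalization, conditional-logistic modelling of 1:1 incidence-density
matched sets, and natural-effect mediation. Because the individual-level
cohort data such studies rest on are access-restricted, the package ships
seeded generators that emulate every input with known ground truth; the
published three-variant instrument table for circulating FABP-4 (fatty
acid binding protein 4) is packaged verbatim as a text fixture.

## Two-sample MR estimators

Inputs are per-variant summary associations: `beta_X` (effect on the
exposure, in trait-SD units, with standard error `SE_X`) and `beta_Y`
(effect on the binary outcome, log-odds, with `SE_Y`), allele-aligned by
the harmonization step so both refer to one effect allele per variant.

- **Wald ratio** (single instrument): `beta_Y / beta_X`, SE by the
  first-order delta method `SE_Y / |beta_X|`. The second-order term
  (`beta_Y^2 SE_X^2 / beta_X^4` added under the square root) is available
  behind a flag and off by default; for strong instruments it changes the
  SE in the third decimal at most.
- **Fixed-effects IVW**: the precision-weighted regression of `beta_Y` on
  `beta_X` through the origin with weights `1/SE_Y^2`. No overdispersion
  scaling by default; a multiplicative random-effects option
  (`max(1, sigma_hat)` inflation) exists behind a flag.
- **Correlated-instrument IVW**: the same regression by generalized least
  squares with outcome covariance `Omega = D rho D`, `D = diag(SE_Y)`,
  for instruments in linkage disequilibrium. `rho` must be supplied
  (signed, unit diagonal, positive definite); the package computes no LD
  from reference panels. Solved via Cholesky factors rather than an
  explicit inverse.
- **MR-Egger**: weighted least squares of `beta_Y` on `beta_X` with a
  free intercept, weights `1/SE_Y^2`, after orienting every instrument to
  `beta_X >= 0` (the slope is orientation-invariant; the intercept — the
  directional-pleiotropy estimate — is only identified under this
  convention). Both SEs are scaled by `max(1, sigma_hat)` with
  `sigma_hat^2 = weighted RSS / (k - 2)`. P-values use the normal
  reference by default; a Student-t reference with `k - 2` df is
  available (`t_dist=True`) because with k = 3 instruments the two
  conventions differ materially and published reports rarely state which
  was used.

All confidence intervals use `z = 1.959964`. Cochran's Q
(`heterogeneity_q`) compares independent stratum estimates (e.g. the
sex-specific per-SD effects) under fixed-effect pooling, with a
chi-square reference at (strata − 1) df.

## Instrument strength and power

Per-variant variance explained defaults to the summary-statistic form
`R^2_j = beta_j^2 / (beta_j^2 + n SE_j^2)`; the allele-frequency form
`2 p (1-p) beta_j^2` (valid for SD-unit betas) is exposed as an
alternative. The se-based form is the default because, on the packaged
fixture, its three-variant total (0.965%) is consistent with the
published "about 1%" and with the published joint F of 65, whereas the
eaf-based total (1.36%) is not.

The joint F-statistic is `((n - k - 1)/k) * (R^2 / (1 - R^2))`. The
source for this design prints the two factors separated by a division
sign; only the multiplicative reading reproduces the published F = 65
(the literal division would give ~7e5), so the multiplicative form is
implemented.

Power for a binary-outcome MR uses the standard normal approximation:
`log OR_min = (z_{1-alpha/2} + z_{power}) / sqrt(N phi (1-phi) R^2)` with
`N` the total outcome-GWAS size and `phi` the case fraction;
`power_at_or` is its exact inverse (round-trip verified to 1e-6 in
tests). Normal quantiles are computed at full precision.

## Enumeration colocalization

Per-variant evidence is the Wakefield approximate Bayes factor on the log
scale: with `V = SE^2`, `z = beta/SE`, `r = W/(W + V)`,
`log ABF = 0.5 log(1 - r) + z^2 r / 2`. Prior effect SDs `sqrt(W)`
default to 0.2 (trait-SD units) for quantitative traits and 0.15
(log-odds) for binary traits — the established enumeration-coloc
convention; the study this design derives from states only the
colocalization prior, not W.

Assuming at most one causal variant per trait, the five hypothesis
weights are `H0 = 1`, `H1 = p1 Σ B1_i`, `H2 = p2 Σ B2_i`,
`H3 = p1 p2 Σ_{i≠j} B1_i B2_j`, `H4 = p12 Σ B1_i B2_i`, normalized to
posterior probabilities PP0–PP4. Defaults are `p1 = p2 = 1e-4` with
`p12 = 1e-5` ("standard") and `p12 = 1e-4` ("relaxed") presets. The
published "prior probability p" is read as p12 — the prior on the
hypothesis corresponding to colocalization — with p1/p2 left at their
conventional values; the reading is a documented choice since the source
does not say whether p1/p2 were also changed. All sums use
log-sum-exp (H3 via a guarded log-difference), so no per-variant Bayes
factor can overflow; posteriors sum to 1 within 1e-10 even with log-ABFs
in the thousands.

PP4 is monotone non-decreasing in p12 (tested on every simulated
dataset). The published posterior percentages themselves are not
reproduction targets: they require restricted regional summary
statistics.

## Conditional logistic regression

Matched sets are carried as a long DataFrame (one row per subject with
`set_id`, `is_case`, `sex`, covariates). The fit maximizes the exact
conditional likelihood `Π_sets exp(x_case' b) / Σ_members exp(x_m' b)` by
Newton–Raphson: gradient-norm tolerance 1e-8, at most 25 iterations,
step-halving whenever a step would decrease the likelihood. Under
incidence-density sampling the exponentiated coefficients estimate
incidence rate ratios and are reported as relative risks.

Numerical and design details:

- Covariates constant within every matched set (the matching factors) are
  flat directions of the conditional likelihood; they are detected,
  pinned at zero, and reported as aliased — adding them changes neither
  the likelihood nor the other estimates (tested).
- For 1:1 sets the fit coincides with no-intercept logistic regression on
  case-minus-control differences; this algebraic identity is the
  dual-route test oracle (statsmodels `Logit` on differences and
  `ConditionalLogit` on 1:2 sets), never the implementation.
- Coefficients beyond ±20 on the log scale flag complete separation;
  non-convergence after the iteration cap is flagged, not silent.
- Sets with no within-set covariate variation are uninformative and do
  not contribute; their count is reported.

**Quintile coding.** Cut-offs are the 20/40/60/80th percentiles of the
control distribution within sex, by linear interpolation (the numpy
default; the rule is configurable since printed category ranges cannot
adjudicate it without raw data). Categories are half-open `[low, high)`
with the top category closed above; when a value ties with more than one
cut-off the assignment resolves downward, so a degenerate all-equal
control distribution puts everyone in the first category. Each subject
also receives the sex-specific control median of their category as a
trend score, and the overall control SD is recorded for per-SD scaling.

**Body-size covariates.** ABSI is
`waist (mm) × weight (kg)^(-2/3) × height (m)^(5/6)` with internal unit
conversions. Waist-circumference residuals come from OLS of waist on BMI
and height (with intercept) over complete cases; subjects missing waist
receive the sex-specific median residual with an imputation flag, and
complete-case analysis is the sensitivity alternative. Set-level
exclusion utilities drop a whole matched set when its case (or any
member) is flagged, mirroring the "cases and their matched controls"
exclusion rule.

**Non-linearity.** The fractional-polynomial scan searches FP1 powers
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 meaning log; repeated FP2 powers add a
log-multiplied copy) inside the conditional model, with the non-linearity
p-value from a 3-df likelihood-ratio test of the best FP2 against the
linear model. Transformed columns are standardized internally (a linear
reparameterization; the maximized likelihood is unchanged) to keep the
Newton iteration well-scaled.

**Spearman partial correlations** rank all variables — x, y, and the
covariates — with average ranks for ties, residualize the ranked x and y
on the ranked covariates by least squares, and report the Pearson
correlation of the rank residuals with a t-based p-value at
`n − n_covariates − 2` df. This matches the SAS/pingouin convention and
is verified against pingouin in tests. The Bonferroni helper takes the
test count explicitly.

## Mediation

`mediate_ncc` uses the product method under a rare outcome and no
exposure–mediator interaction: a linear mediator model (slope `alpha1`)
fitted among controls — treated as representative of the risk-set
population under incidence-density sampling — and a conditional-logistic
outcome model with both exposure and mediator. Then
`log NDE = beta_exp · delta`, `log NIE = alpha1 · beta_med · delta`, the
total is their sum, and the proportion mediated is `log NIE / log total`
(undefined and returned as missing when the total is null). A
whole-sample mediator-model option exists with the caveat that cases are
over-represented relative to the source population; both options are
exposed rather than guessing a single intent, since the nested-design
weighting is not pinned down by the source. Percentile intervals come
from a seeded nonparametric bootstrap over matched sets (default 500
resamples when enabled); the decomposition itself reports no interval by
default.

## Synthetic-data generators

All generators are bit-reproducible given their params and an integer
seed; one root seed fans out to independent child streams per component.

**Cohort.** Sex-specific log-normal biomarker with control medians
12.1 ng/mL (men) and 18.3 ng/mL (women) and a common log-scale SD of
0.45, which makes the overall control SD ≈ 8.8–8.9 ng/mL — the published
calibration targets. Part of the log-biomarker variance (correlation 0.4)
is routed through BMI to give a realistic confounding structure.
Confounders: age N(58, 7) clipped to [35, 75], 8 centers, education /
activity / smoking categories, log-normal alcohol, sex-specific height
and BMI, and waist regressed on BMI and height plus noise. Event times
are exponential with log-rate linear in the standardized biomarker plus
age and sex terms; by default the only unmatched determinant of risk is
the biomarker itself, so the matched design is unconfounded by
construction and the design-validity recovery checks isolate the
sampling scheme rather than adjustment choices. Baseline hazard
0.004/year over a 12-year horizon gives ~4–5% cumulative incidence (rare
outcome). Setting the mediator-path triple (`alpha1`, `beta_mediator`,
`beta_exposure`) switches the biomarker to a linear mediator of waist
with residual SD 6 ng/mL and puts the direct and mediated effects in the
hazard explicitly.

**Incidence-density matching** draws, for each case in event-time order,
one control uniformly from the risk set: event-free at the case's event
time, same sex and center, age within a ±2-year caliper (a configurable
stand-in for center-specific matching protocols). A sampled control may
later become a case; cases with empty risk sets are dropped and counted.
No future information is used (tested).

**Two-sample GWAS.** Genotypes Binomial(2, EAF) in two independent
samples; the exposure is unit-variance with the target R² split equally
across variants; the binary outcome follows a logistic model with the
true causal log-OR per exposure SD plus optional per-variant direct
(pleiotropic) effects. Summary statistics are per-variant OLS (exposure)
and vectorized logistic score-test estimates (outcome) — asymptotically
equivalent to per-variant MLEs at these sample sizes. Default simulation
EAFs are 0.2/0.3/0.4: recovery runs probe estimator behaviour at common
frequencies rather than replicating the fixture's extreme frequencies,
where single-replicate summary statistics are dominated by the handful of
minor-allele carriers.

**LD regions** use haplotype-copying Markov chains (copy the previous
allele with probability `rho_LD`, else a fresh Bernoulli draw), giving
dosage autocorrelation exactly `rho_LD^|i-j|` for a shared allele
frequency — a hard Gaussian threshold would attenuate the correlation
well below its nominal value. Traits are driven by designated causal
variants under shared / distinct / none configurations with the truth
recorded.

What the generators do **not** emulate: real haplotype structure or
allele-frequency spectra, center-specific matching protocols, the full
covariate battery of a multi-center cohort (diet, repeated biomarkers),
measurement error in the biomarker, or non-proportional hazards. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated models, not robustness to the full messiness of real cohort
data.

## Problem sizes in the routine checks

The stochastic consistency suites use 200 replicates for two-sample MR
recovery (k = 3, 20,000 exposure GWAS, 20,000 cases / 20,000 controls),
500 reduced-scale replicates (5,000/5,000/5,000) for Egger test-size
calibration, 50 replicates per causal configuration for regional
colocalization (m = 50, rho 0.8, n = 10,000 per trait), 100 replicates of
1,000 matched sets for the incidence-density design check, and 200
replicates of ~1,000 matched sets for mediation recovery — sizes chosen
so each suite completes in minutes on one CPU while leaving Monte-Carlo
error well below the effects being verified.

## Known limitations

- No weighted-median/mode estimators, MR-PRESSO, or Steiger filtering;
  no SuSiE-style multi-causal colocalization or credible sets.
- Palindromic-variant handling is frequency-based and cannot rescue
  genuinely ambiguous variants (minor-allele frequency near 0.5); they
  are dropped under the default policy.
- The mediation decomposition relies on the rare-outcome approximation
  and the no-interaction assumption; neither is checked internally.
- Genome-build liftover is out of scope; positions are taken as given.
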