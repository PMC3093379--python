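# Methods

## Scope and model

The package studies the sampling behavior of genomic control
λ = median(χ²)/0.4549 and QQ-plots in genome-wide gene–environment
interaction scans under the *strong null*: every simulated phenotype is
generated without reference to genotype, so all per-locus interaction
tests are null by construction. Each locus is fitted with the interaction
regression

    g(E[Y]) = β₀ + β_E E + β_G G + β_GE (G×E) [+ covariates],

with identity link (least squares), logit link, or the Cox log-hazard
(no intercept), and the Wald statistic (β̂_GE/SE)² is referred to χ²₁.
Every fit carries two covariance estimates: the classical model-based one
and the estimating-equation sandwich A⁻¹BA⁻¹.

The central fact the package makes measurable is a variance-accounting
one. Across a genome scan, (Y, E) are one fixed realization and only G
varies, so the empirical spread of β̂_GE entering λ's numerator is
Var(β̂_GE | Y, E). By the law of total variance,

    Var(β̂_GE) = Var_{Y,E}(E[β̂_GE | Y,E]) + E_{Y,E}(Var(β̂_GE | Y,E)),

and the first term is numerically negligible for least-squares interaction
scans (the `decomp` module verifies this by direct simulation rather than
proof), so the genome-wide spread matches the *unconditional* variance —
the quantity the sandwich estimates. Model-based standard errors estimate
the variance over Y given (G, E); the analogous split conditioning on
(G, E) has a first term that vanishes only when the mean model is correct.
Under mis-specification the model-based denominator is therefore too
small and λ inflates with no confounding present.

## Simulated cohorts

* **Exposure** E ~ Normal(0, 1) i.i.d. (mean/sd configurable).
* **MAF law**: beta(α=0.5, β=0.5) truncated at 0.5 and floored at 0.02, by
  rejection sampling (exactly the restricted density).
* **Genotypes**: G_j ~ Binomial(2, MAF_j), i.e. Hardy–Weinberg biallelic
  loci coded as minor-allele counts; loci independent (no LD).
* **Stratification** (optional): subjects are assigned to subpopulations
  (default 20%/80%); each locus has a central MAF p and per-subpopulation
  MAFs drawn from the Balding–Nichols law Beta(p(1−F)/F, (1−p)(1−F)/F)
  with Wright's F_ST = F (default 0.01), which has mean p and variance
  F·p(1−p). Confounding of the interaction test is induced by giving the
  subpopulations different linear exposure slopes while the quadratic term
  is shared.
* **Phenotype models** (genotype never enters):
  * linear family — Y = β₀ + bE (+ cE²) + ε with ε ~ N(0, noise_sd²), or
    heteroskedastic ε·(1+|E|), or the exponential curve
    Y = a·exp(bE) + ε (amplitude a stored in the intercept slot);
  * logistic family — Y ~ Bernoulli(expit(β₀ + bE + cE²));
  * survival family — event time ~ Exponential(rate = exp(β₀ + bE + cE²)),
    administratively censored at the empirical (1−target) quantile of the
    event times (target 0.5 censors at the median survival time); a
    Uniform(0, 2·median) censoring-time mode is also provided as the other
    common way to target ~50% censoring. The fixed cutoff is the default
    because it hits the target censored fraction exactly in expectation
    and keeps the scan deterministic given the cohort.

Default scenario coefficients (all configurable; `presets.py`): correct
model Y = E + ε; quadratic Y = E + E² + ε; heteroskedastic Y = E + ε(1+|E|);
exponential Y = exp(E) + ε; logit-quadratic −1 + E + 0.5E²; log-hazard
quadratic E + 0.5E²; confounded scenario slopes 1.2 (20% subpopulation)
vs 1.0 (80%) with shared quadratic 0.5 at F_ST = 0.01. These produce
clearly visible model-based inflation at n = 1,000 without numerical
overflow. Default sizes are n = 1,000 subjects and m = 10,000 loci
(m = 2,000 for the slower logistic/Cox scans).

Cohorts are reproducible bit-for-bit from the config seed; the genotype
matrix is drawn in a single vectorized call from one seeded generator
(draw order: subpopulation labels, central MAFs, subpopulation MAFs,
genotypes, exposure, phenotype).

## Estimators

* **Linear**: OLS per locus, vectorized across loci (batched normal
  equations; algebraically identical to the single-locus path, which is
  tested). Model-based covariance σ̂²(XᵀX)⁻¹. Sandwich
  (XᵀX)⁻¹(Σᵢ xᵢxᵢᵀ wᵢrᵢ²)(XᵀX)⁻¹ with HC0–HC3 weight flavors; **HC3**
  (wᵢ = (1−hᵢ)⁻²) is the default. Calibration measured at n = 1,000 over
  replicate null scans: HC1 gives robust Wald type-I error 0.056–0.066 and
  λ_robust means 1.03–1.12 across the three linear scenarios, HC3 gives
  0.052–0.056 with λ centered near 1 — at genome-scan n in the low
  thousands the flavor is *not* immaterial, and the leverage-corrected
  flavor is the standard small-sample recommendation.
* **Logistic**: IRLS (statsmodels GLM), score-norm convergence check at
  10⁻⁸, 25 iterations; separation detected (fitted probabilities equal to
  the outcomes, or diverging linear predictor) and flagged rather than
  raised. Model-based covariance: inverse Fisher information (= observed
  information under the canonical logit). Sandwich: A⁻¹BA⁻¹ with
  B = Σ xᵢxᵢᵀ(yᵢ−μ̂ᵢ)²/(1−hᵢ)², hᵢ the weighted-design hat value — the
  same leverage correction as linear HC3 (Mancl–DeRouen-style), chosen for
  the same measured reason (plain-sandwich λ_robust mean ≈ 1.05 at
  n = 1,000 vs ≈ 1.01 corrected); the plain HC0 form is selectable.
* **Cox**: Newton–Raphson on the Breslow partial likelihood (step-halving
  on likelihood decrease, gradient tolerance 10⁻⁸, max 25 iterations),
  risk sets via a shared sort structure so a scan costs O(nk²) per locus.
  Model-based covariance: inverse observed information. Robust covariance:
  the Lin–Wei sandwich I⁻¹(Σᵢ ŝᵢŝᵢᵀ)I⁻¹ from per-subject score residuals,
  kept unadjusted — no established leverage-type correction exists for the
  Cox sandwich, and the implementation reproduces `survival::coxph`
  (ties="breslow", robust=TRUE) to ~10⁻⁷ on fixtures.
* **Tests**: 1-df Wald on β_GE for either SE flavor; likelihood-ratio
  tests for nested linear/logistic fits; 2-df joint Wald on the (G, G×E)
  block of either covariance.
* **Scan hygiene**: loci with minor-allele count < 5 are flagged
  `low_mac` and excluded from λ (sandwiches need enough carriers to be
  estimable); failed fits are flagged `not_converged`; loaded data with
  missing hard calls are handled per-locus complete-case.

## Principal components

Locus columns are centered by 2p̂ and scaled by √(p̂(1−p̂)) (the GWAS
standard; unscaled centering is available), monomorphic loci excluded.
Scores are the top-k left singular directions scaled by singular values,
computed from the eigendecomposition of the n×n genetic relationship
matrix; signs are fixed (largest-magnitude entry positive) so outputs are
platform-reproducible. Default k = 1, matching the two-subpopulation
scenario where PC1 correlates > 0.99 with the subpopulation label.
PC adjustment enters the scan as main-effect covariates; an optional flag
adds PC×E products (the full adjustment when ancestry modifies the
exposure effect). At F_ST = 0.01 with slope difference 0.2 the two choices
are indistinguishable within Monte-Carlo noise, so the default follows the
simpler main-effect form.

## Genomic control and QQ coordinates

λ is computed from the χ² statistics directly (not from re-inverted
p-values) as median/0.4549, the conventionally printed 4-dp constant; the
full-precision χ²₁ median (0.45493642…) is kept alongside for reference.
Expected QQ quantiles use Hazen positions (i−0.5)/m. GC correction divides
statistics elementwise by λ.

## The decomposition experiment

`run_decomposition` measures the spread of β̂_GE under three
randomization regimes at the same scenario: everything redrawn;
(Y, E) held fixed while G is redrawn (the regime a QQ-plot actually
displays); and (G, E) held fixed while Y is redrawn (the regime
model-based errors describe). The genotype is a two-group indicator by
default (frequency 0.3; 0/1/2 coding available). Defaults
n_outer = 50 instances × n_inner = 200 replicates at n = 500 keep
Monte-Carlo error inside the 10% tolerances used in the tests while
finishing in seconds. Summaries are numeric (variances, between-instance
terms, per-arm draws as a table), not images. Under the exponential
scenario β̂_GE is heavy-tailed, so variance estimates from 50 instances
carry visibly more noise; the tests assert the ordering and magnitude
rather than tight ratios there.

## Monte-Carlo behavior of λ (what a single scan can and cannot show)

With m i.i.d. null statistics the sample median alone gives λ a standard
deviation of ≈ 0.023 at m = 10,000 (≈ 0.052 at m = 2,000). On top of that,
the loci of one scan share a single (Y, E) realization, and the
conditional median shifts with realized fourth-moment couplings of
exposure and noise: under the correct linear model λ_model fluctuates
with sd ≈ 0.06 at n = 1,000, and the logit-quadratic scenario shows a
similar conditional wobble for both flavors. A single-scan λ inside
[0.97, 1.03] is therefore *not* guaranteed by a calibrated estimator, nor
does a value of 1.05 indicate miscalibration; judgments about an
estimator should average over replicate cohorts (as the calibration
studies behind the flavor defaults do). Under the strong quadratic
mis-specification (c = 1) even the HC3 sandwich retains a small upward
λ bias (mean ≈ 1.035 at n = 1,000) — robust variances fix the first-order
problem (λ_model ≈ 3–5) but are not exact in finite samples.

## What the simulations do and do not emulate

Simulated cohorts have independent loci (no LD), complete hard-call
genotypes, exactly Normal exposure, and at most a two-subpopulation
admixture-free structure. Passing tests therefore demonstrate the
variance-accounting phenomenon and its remedies in clean conditions; they
do not speak to LD-induced correlation between test statistics, imputed
dosages, case-control ascertainment, kinship/mixed-model settings, or
exposures with heavy tails — all of which can move λ for separate
reasons. Real-data input paths (TSV/VCF) reuse the identical per-locus
machinery, with per-locus complete-case handling as the only addition.

## Numerical choices and degenerate inputs

Convergence tolerances are gradient-norm 10⁻⁸ with 25 iterations and
step-halving (logistic, Cox); OLS is closed-form with a rank check.
Hat values are clipped below 1 before (1−h) weighting. Reported p-values
are floored at 10⁻³⁰⁰ to stay in (0, 1]. Zero-SE fits (exact
interpolation) yield flagged, undefined Wald tests instead of division
errors. Empty scans, all-monomorphic PCA inputs, single-class logistic
outcomes, and event-free survival data raise typed errors or flagged
fits as documented in the API. F_ST = 0 returns the central MAF
replicated (the exact no-drift limit) with a logged note.
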