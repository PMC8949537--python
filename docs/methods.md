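# Methods

## Scope and data model

The package analyses the relationship between dietary macronutrient
intake and cardiometabolic outcomes along two arms that share nothing
but a scientific question: a mediation arm operating on
individual-level cohort tables (one row per participant: diet in g/day,
total energy intake in kcal/day, mediators BMI kg/m² and physical
activity scores, confounders, continuous traits in mmol/L, binary
disease indicators), and an MR arm operating on per-variant GWAS
summary statistics (SNP, alleles, effect-allele frequency, beta, SE, p,
N in the conventional TSV layout). Both arms are exercised end to end
against synthetic data whose generating parameters are known, so each
estimator is validated by parameter recovery rather than by comparison
with irreproducible external numbers.

## Dietary preprocessing

Raw intakes are right-skewed; the pipeline log-transforms after adding
a constant 0.1 (so zero intakes stay defined), then removes the
energy-intake signal with the Willett residual method: the transformed
nutrient is regressed on total energy intake and the residuals are
re-centred at the nutrient mean. The residual output is exactly
uncorrelated with TEI (a property test asserts |r| below 1e-10).
Energy percent uses metabolizable-energy conversion factors; the
defaults are the Atwater values (4 kcal/g protein and carbohydrate,
9 fat, 7 alcohol) and are configurable. Added sugar is sucrose plus
monosaccharides minus fruit/vegetable sugars, clamped at zero because a
negative intake is physically meaningless; total sugar is all mono-
plus disaccharides. LDL-C uses the Friedewald formula
(TC − HDL − TG/2.2) with a validity bound of TG ≤ 4.5 mmol/L, above
which the value is set missing and flagged. Participants on
lipid-lowering medication get published additive corrections
(+0.208 TG, +1.347 TC, −0.060 HDL, +1.290 LDL, mmol/L); untreated rows
are untouched, so re-running the correction with the flag cleared is a
no-op. Nutrient patterns come from PCA of the centred-and-scaled
nutrient matrix (eigenstructure of the correlation matrix, top three
components retained by default, variance fractions reported for all).
Record exclusion is rule-driven (per-variable ranges and flags, YAML
config); the shipped ranges are generic adult plausibility screens, not
cohort-specific limits, because real cohort outlier bounds are a data
manager's call.

## Mediation arm

Estimation is equation-by-equation for the recursive observed-variable
path system: OLS for every mediator equation and for a continuous
outcome, ML logistic regression for a binary outcome equation. For a
recursive system without latent variables this coincides with joint ML
in the linear case, and it keeps each equation inspectable. The three
configurations are pairwise (one mediator), parallel (two mediators,
no cross-path) and serial (mediator 1 feeds mediator 2 through a path
d, contributing the chained indirect product a1·d·b2). On any common
complete-case sample with a continuous outcome, total = direct + sum of
indirect products holds algebraically, and equals the exposure
coefficient of the no-mediator regression; the test suite asserts this
to 1e-10 and the acceptance script measures it at ~1e-16.

Composite-effect inference uses nonparametric case-resampling bootstrap
of whole participant rows (preserving the X–M–Y dependence), with
percentile intervals at the configured level and SE the SD across
draws. The default draw count is 5000; the validation studies use 1000
for a 200-cohort coverage study, which is ample for 95% percentile
intervals. Resamples in which any design column degenerates to a
constant are skipped and logged; more than 10% skipped aborts the run.
The bootstrap refits by solving the normal equations on one Gram matrix
per resample rather than calling the regression framework per draw;
this is an implementation choice that makes a 200 × 1000-draw coverage
study run in about a minute.

Binary outcomes additionally get probability-scale average mediation
effects by the potential-outcomes simulation estimator: coefficient
vectors are drawn from their asymptotic normal distributions, mediator
values are simulated (with residual noise) under the observed exposure
and under a one-unit increase, and the model-implied outcome
probabilities are averaged over participants and draws. ACME is
E[Y(x+1, M(x+1)) − Y(x+1, M(x))], ADE is E[Y(x+1, M(x)) − Y(x, M(x))],
so the two add exactly to the total probability change. Linear-predictor
scale products are also reported, since the scale of a logistic "total
effect" is a genuine ambiguity — both are emitted rather than choosing.

The nested-model test compares the outcome equation with and without
the direct path (c′ = 0) by a likelihood-ratio chi-squared statistic on
1 df. For these recursive observed-variable systems the exposure term
is the only difference between the partially and fully mediated
models, so the outcome-equation test and a system-level test coincide.
Measured type-I error is ~5% at n = 1000 over 500 replicates.

Collinearity screening reports VIF_j = 1/(1 − R²_j) per covariate with
a removal flag at 10 (perfect collinearity reported as infinite, never
silently dropped). Multiple testing across a mediation grid uses
Benjamini–Hochberg step-up adjustment at q = 0.05, applied within each
effect column across the grid. Cardiovascular outcomes are additionally
adjusted for tobacco use when the column is present. Grid cells that
fail (e.g. a zero-variance exposure) are marked and logged; the sweep
continues.

## MR arm

Instrument selection keeps variants with p below the threshold
(default 5e-6, reflecting the reality that diet GWAS yield few
genome-wide-significant hits) and then clumps greedily: retain the
lowest-p variant, drop everything within ±1000 kb at r² ≥ 0.2 with it,
repeat. Clumping requires a user-supplied LD matrix (entries read as
r²; symmetric, unit diagonal); without one the p-filter alone applies
and a log line says so. A derived "adjusted" instrument for separating
correlated exposures (e.g. carbohydrate net of sugar) is the union of
two selected sets minus their overlap, the overlapping variants being
removed on pleiotropy grounds.

Harmonization inner-joins on variant id, aligns the outcome record to
the exposure effect allele (flipping beta and EAF when alleles are
swapped, resolving strand flips via complements), removes all
palindromic A/T and C/G variants regardless of frequency (no frequency
rescue — ambiguity is not worth the bias risk at these instrument
counts), and removes unresolvable allele pairs. Every variant's action
is recorded, and harmonizing an already-harmonized pair is a no-op.

Estimators, with the numerical choices that matter:

- **IVW**: weighted regression of outcome betas on exposure betas
  through the origin, weights 1/σ_Y². SE is multiplicative
  random-effects with the residual scale floored at 1 — it can never
  undercut the fixed-effects SE. k = 1 reduces exactly to the Wald
  ratio (special-cased so the equality is bitwise). Cochran's Q on
  k − 1 df.
- **MR-Egger** (k ≥ 3): weighted regression with intercept after
  orienting every variant to β_X ≥ 0, which the intercept needs for
  identifiability. Same SE convention; Q on k − 2 df. The intercept
  estimates mean directional pleiotropy under InSIDE; recovery of a
  planted 0.05 requires the orientation to be meaningful, which is why
  the validation study draws positive exposure effects.
- **Weighted median** (k ≥ 3): per-variant ratios ordered, weights
  β_X²/σ_Y² (first-order inverse ratio variance), linear interpolation
  of the weighted cumulative distribution at 0.5. SE by seeded
  parametric bootstrap (default 1000 draws) resampling both summary
  betas from their normal distributions.
- **MR-RAPS** (k ≥ 3): maximizes the profile likelihood of θ treating
  exposure betas as noisy, with overdispersion τ² ≥ 0 absorbing
  balanced pleiotropy; squared or consistency-corrected Huber loss
  (correction factor 2Φ(c) − 1 keeps τ̂² consistent under the robust
  loss). Multi-start L-BFGS-B; SE from a sandwich built out of
  per-variant numerical scores. Non-convergence raises with
  diagnostics rather than returning a silent number.
- **MR-PRESSO** (k ≥ 4): the observed weighted residual sum of squares
  of each outcome beta against its leave-one-out IVW prediction is
  compared with parametric simulations under the fitted model (default
  1000 draws; the validation studies use 500). Per-variant
  contributions give the outlier test (Bonferroni at 0.05); the
  distortion test compares the outlier-removal shift against removals
  of random variant sets; the corrected estimate is IVW on
  non-outliers. The leave-one-out predictions are computed from Gram
  sums, so the simulation is fully vectorized. Null calibration was
  verified: the global p is uniform under clean data (KS p ≈ 0.4 over
  200 replicates).

Binary (logistic) outcome effects are estimated on the log-odds scale
and exp-transformed to odds ratios afterwards, CI bounds included.
Per-variant instrument strength is F = (β_X/σ_X)², summarized by the
median, which is the honest summary when instruments are few and weak.
Leave-one-out flags variants whose omission moves the IVW estimate by
more than one SE of the re-estimate. The overall verdict is
deliberately conservative: significance requires directional agreement
of IVW, weighted median and MR-Egger with p < 0.05 each and a PRESSO
global p > 0.05; if the consistency methods cannot run (k < 3) the
verdict is "not significant".

## Synthetic-data generator

The cohort generator draws independent standard-normal confounders with
declared loadings, an exposure, then mediators and outcome from the
recursive linear system; binary outcomes pass the linear predictor
through an inverse logit with intercept −2.2 (≈10% baseline prevalence,
a realistic register-linkage disease rate). Residual SD defaults to 1,
so path coefficients read as standardized effects. The GWAS generator
draws per-variant exposure effects γ_j (default N(0, 0.05²), or
user-supplied), standard errors from the standard approximation
σ ≈ 1/√(2N·maf(1−maf)) with maf ~ U(0.05, 0.5) and N defaulting to
250,000 (consortium scale), exposure betas N(γ_j, σ_X²) and outcome
betas N(θγ_j + α_j, σ_Y²). Pleiotropy regimes: none (α = 0), balanced
(mean exactly 0), directional (mean exactly μ_α), and an
InSIDE-violating mode correlating α with γ. A tenth of variants carry
palindromic alleles by default so harmonization filters are always
exercised; variants sit 1 Mb apart so default clumping treats them as
independent.

What the generator does **not** emulate: LD between instruments beyond
a user-supplied matrix, genotype-level data, selection/collider
structure, measurement error in FFQ-derived intakes, non-normal
confounding, or sample overlap between the two GWAS. Passing recovery
tests therefore demonstrates the estimators are correct under their own
assumptions — not that those assumptions hold in any particular cohort.

## Validation study sizes

The shipped studies use 200 cohorts of n = 5000 with 1000 bootstrap
draws for mediation recovery and coverage, 500 replicates for the
nested-test calibration and the MR estimator-bias battery (k = 50,
median F in the hundreds), 200 replicates for Egger-intercept recovery
and PRESSO null calibration (n_sim = 500), and 100 replicates for
planted-outlier detection. These sizes put Monte-Carlo error well below
every acceptance band while keeping the full validation under a few
minutes on one CPU.

## Known limitations

- Mediation assumes sequential ignorability; nothing in the data can
  certify it, and the package does not attempt sensitivity analysis for
  unmeasured mediator-outcome confounding.
- The serial configuration fixes the mediator order; reversing it is a
  different model the user must specify.
- MR proxies (borrowing a correlated variant for one missing in the
  outcome GWAS) are not implemented; missing variants are dropped and
  logged. An LD matrix only drives clumping.
- The logistic "total effect" scale ambiguity is resolved by reporting
  both linear-predictor and probability scales, not by choosing one.
- MR-RAPS inference near the τ² = 0 boundary uses the same sandwich as
  in the interior, which is mildly conservative there.
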