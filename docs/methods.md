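# Methods

This note records the statistical models the package implements, the
defaults and conventions that matter for reproducing its behaviour, and
what the synthetic-data suites do and do not demonstrate.

## Study designs and data model

A dataset is a long table of measurements: subject identifier, real-valued
time stamp, target, and p feature columns. Four designs are supported,
crossing a temporal (per-measurement, continuous) versus static
(per-subject, categorical) target with longitudinal (repeated subjects)
versus distinct (one occasion per subject) sampling. Designs may be
unbalanced — subjects can have different numbers of occasions — and time
is used as the actual stamp τ, never as a factor. The occasion index
needed for autoregressive lags is the within-subject rank of the distinct
time stamps; aligning unbalanced designs by rank order is a convention,
not a property of the data.

Validation enforces at least three distinct time values for the temporal
designs (time enters the mean model as a covariate, and fewer points give
it no room) and at least two for the static designs (a per-subject slope
needs two points). Held-out cross-validation folds are exempt from these
minima: a single held-out time point is predicted, never fitted.

## Conditional independence tests

All tests are nested-model coefficient tests of Ind(X; T | Z) and share
three conventions:

1. **Feature columns are standardised internally** before entering any
   design matrix. Coefficient tests are invariant to affine rescaling of
   predictors in exact arithmetic; standardising makes the fitted
   iteration paths identical in floating point as well, so p-values are
   invariant to measurement units to ~1e−12 relative.
2. **Rank degeneracy returns p = 1** rather than raising: if X adds no
   new direction to the span of [1, τ, Z] (relative squared residual
   below 1e−10), the test reports "no new information". This keeps the
   search safe on collinear candidates and is what makes substitute
   detection possible.
3. p-values are carried with their natural logarithm (`log_p`) so ranking
   stays stable after underflow.

### Temporal-longitudinal: mixed-model F

The full model `T = a + b_i + γτ + δZ + βX` with a subject random
intercept is fitted by maximum likelihood (not REML: a single model is
fitted and a single-coefficient statistic formed, so the variance estimate
should be the one consistent with the fixed-effect covariance). The
likelihood is profiled over ψ = σ_b²/σ²: for fixed ψ the model is GLS
with V_i = I + ψJ, invertible in closed form by Woodbury, so the fit is a
bounded one-dimensional optimisation. A value-only search localises ψ to
~√ε; a final root-solve on the analytic stationarity condition polishes it
to full precision (this is what delivers the unit-invariance above).
Random slopes are deliberately not offered — with 3–6 time points they
overfit — and no AR(1) structure is placed inside the mixed model.

The statistic is F = (β̂/se(β̂))² with se from the GLS covariance
σ̂²(X′V⁻¹X)⁻¹, referred to F(1, N − K − P + 1), the innermost-grouping
denominator convention of the mixed-model literature. The F calibration
is preferred over the likelihood-ratio χ² because it controls type-I
error better at small K. Fixed-effect estimates, variances and
log-likelihoods agree with an independent ML mixed-model implementation
to ≤1e−4; standard errors differ by up to a few percent because the
reference derives them from the observed information rather than the GLS
form. `random_intercept=False` collapses the test to the classical OLS
partial F on (1, N − P), which the tests verify against a closed-form
oracle to 1e−6.

### Temporal-longitudinal: GEE Wald

The marginal model drops b_i and is fitted by iterated generalised least
squares with a working correlation — exchangeable (CS: constant
correlation α) or AR(1) (α^|j−j′| in occasion-rank lag). α is estimated
by method of moments on Pearson residuals each iteration, clipped into
its feasible range (α > −1/(max nᵢ − 1) for CS, |α| < 1 for AR(1)) with a
warning; iteration stops at relative parameter change < 1e−6 or 25
iterations. With one occasion per subject the working correlation is
vacuous and the solution is exactly OLS (verified to 1e−6 against the
closed form).

The default variance of β̂ is the leave-one-subject-out jackknife with
one-step updates from the full-data solution:

    β̂₍₋ᵢ₎ = β̂ + (A − Aᵢ)⁻¹(−sᵢ),
    Var = (K − P)/K · Σᵢ (β̂₍₋ᵢ₎ − β̂)(β̂₍₋ᵢ₎ − β̂)′,

where Aᵢ and sᵢ are subject i's information and score pieces. This
estimator is designed for small subject counts (K ≤ 30); it is known to
be somewhat liberal there, which is why the calibration suite allows the
GEE tests a wider type-I band ([0.02, 0.08] versus [0.03, 0.07]) at
K = 25, d = 4. At larger K or with the model-based variance
(`variance="model"`, φ(X′V⁻¹X)⁻¹) the level tightens toward nominal.

### Static-longitudinal: two-stage LRT

Stage one reduces every subject × feature trajectory to a least-squares
intercept and slope on τ, assembling a K × 2p matrix Γ (feature-major,
intercept before slope; a subject with a single distinct time is an
error). Stage two fits nested logistic (2 classes) or multinomial (C > 2)
models of the label on the Γ column pairs of Z versus Z plus X and refers
2(ll₁ − ll₀) to χ² with 2(C − 1) degrees of freedom. The stage-two models
contain no time main effect: time is already absorbed into the
per-subject summaries, and the label is constant within subject. Perfect
separation — common at K ≤ 30 with strong class differences — triggers a
bounded BFGS fit with a warning rather than a failure; the statistic is
taken from the converged deviances. The LRT statistic is verified to
1e−4 against brute-force maximisation of both Bernoulli log-likelihoods
by a generic optimiser.

### Distinct designs

With nᵢ = 1 there is no within-subject correlation to model: the
temporal-distinct test is the ordinary partial F between
`T ~ 1 + τ + Z` and `T ~ 1 + τ + Z + X` on (1, N − |Z| − 3) degrees of
freedom (equal to the squared-t test when Z is empty), and the
static-distinct test is the same comparison through a logit link, with a
likelihood-ratio χ² on C − 1 degrees of freedom.

## The search

The forward max-min search is pinned precisely because reasonable
variants differ in tie cases:

- Univariate tests for all p features come first and are cached
  (statistic and log p per feature). Features with univariate p ≥ a are
  discarded permanently.
- Each iteration evaluates, for every remaining candidate X, the new
  conditioning subsets of the selected set S — those containing the most
  recently selected feature, sizes up to k, smallest first, lexicographic
  within a size (subsets not containing the newest feature were tested in
  earlier iterations; the cached maximum carries them). A candidate is
  dropped at its first p ≥ a.
- Among survivors, the next selection minimises the maximal association
  p over all tested subsets; ties break on the log-p of the maximising
  test, then on the lower feature index. All tie-breaks are total orders,
  so identical inputs give identical results.
- **Substitute rule.** When X is dropped with witness Z, each Y ∈ Z is
  tested against (Z ∖ {Y}) ∪ {X}; if that p ≥ a, X is recorded as a
  substitute of Y. Signatures enumerate the cross-product of
  {Y} ∪ substitutes(Y) over the selected set, lexicographically, capped
  at `max_signatures` (default 100, bounding the combinatorial
  explosion); a combination that would use one feature twice is skipped.
- There is no backward pruning by default — elimination happens
  repeatedly during growth. An optional `backward=True` pass re-checks
  every selected feature against the subsets of the final selected set.
- Re-running with new hyper-parameters (`rerun_with_config`) reuses the
  cached univariate table after verifying a fingerprint of the data and
  test identity; the standard six-configuration grid therefore costs one
  univariate sweep in total.

On instances small enough for exhaustive elimination (p ≤ 8, k = p − 1)
the selected set coincides with an independent brute-force
re-implementation; the test count grows linearly in p at fixed selected
set size.

## Evaluation protocol

Folds never split a dependence unit: whole subjects are held out in the
static-longitudinal design, whole time points otherwise; units are
shuffled by seed and dealt round-robin, m defaults to 4 so every fold
keeps at least two measurements. Per fold and configuration the search
runs on the training rows, the *first* (lexicographically smallest)
signature is fitted with the mirror model of the equipped test — mixed
model for the mixed-model test (predictions add estimated subject
intercepts for known subjects, zero for new ones), marginal GEE for the
GEE tests, logistic/multinomial on the selected Γ columns for the
two-stage test, plain linear/logistic otherwise — and the held-out fold
is scored with MSPE (continuous) or PCC (classification, reported in
[0, 1]). An empty signature falls back to the baseline model
(intercept + time, or the training majority class).

The TT correction takes θ̂ as the configuration with the best column
mean (ties to the lowest index), θ̂ᵢ as each fold's own best, and
averages the per-fold gap; the corrected performance is naive + bias.
For error metrics the bias is ≥ 0 and the correction penalises; for score
metrics the same formula yields a bias ≤ 0, again penalising. The
formula is written for error metrics and the sign interchange for scores
is our reading of its symmetric extension.

Two comparison utilities mirror how competing modeling approaches are
contrasted: a paired permutation t-test (within-pair sign flips, exact
enumeration when 2ⁿ fits in the permutation budget, otherwise seeded
Monte-Carlo with the add-one convention) and a one-sided asymptotic
z-test that a win proportion exceeds one half. The z-test uses the
estimated-variance denominator p̂(1−p̂)/n; on 91 wins in 160 trials it
gives p = 0.03955, the value the tests pin (the null-variance form gives
≈ 0.041 instead).

## Synthetic data

The generators draw data with exactly the structure each test assumes,
plus ground truth, so calibration, power and recovery suites need no
external data:

- `gen_temporal_longitudinal` — balanced K × d design; features carry a
  per-subject random level (variance 0.3), a mild common time trend and
  i.i.d. noise (total variance ≈ 1, so `beta_scale` reads as a
  standardised effect); the target follows the random-intercept model
  with CS or AR(1) residual correlation. Defaults K = 20, d = 4,
  σ_b² = 0.5, σ² = 1, ρ = 0.3 mirror small longitudinal omics studies.
  `n_duplicates` appends exact copies of relevant features to engineer
  equivalence classes.
- `gen_static_longitudinal` — two balanced classes of per-subject linear
  trajectories; relevant features differ between classes in intercept or
  slope (`effect_kind`), so the signal lives exactly in the Γ summaries.
- `gen_distinct` — one measurement per subject spread over d time points;
  linear target in τ and the relevant features, or a logit model for
  binary/multinomial labels.

Feature trajectories deliberately contain subject-level structure:
with i.i.d. features the within-subject machinery would be
indistinguishable from OLS and the calibration suites vacuous. What the
generators do **not** emulate: microarray noise models, probe-level
structure, heavy tails, missing-not-at-random patterns, or correlated
blocks of irrelevant features. Passing recovery tests therefore
demonstrates correctness of the algorithms under their own assumptions,
not performance on real expression data.

## Problem sizes used by the checks

The calibration suites use 500 null replicates per test at K = 20–30,
d = 4 (the small-subject regime the tests target); the recovery benchmark
uses p = 200 features, 4 relevant, K = 30, d = 5, 50 replicates; the
scaling check drives a stub test to p = 10⁴. These sizes make the whole
suite run in about a minute on one CPU while keeping every binomial
confidence band meaningful.

## Known limitations

- The mixed model offers random intercepts only; heavily crossed or
  nested designs are out of scope.
- GEE jackknife Wald tests are liberal at very small K; prefer the
  mixed-model F there.
- The two-stage test summarises trajectories linearly; curvature that
  distinguishes classes beyond intercept and slope is invisible to it.
- Signatures are neighbours-only approximations of a full Markov
  blanket; spouse recovery is intentionally not attempted.
- The substitute rule is a heuristic definition of statistical
  equivalence; equivalence classes are not guaranteed to be transitive,
  and overlapping substitute sets can make some cross-product
  combinations invalid (these are skipped).
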