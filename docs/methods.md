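# Methods

## Model

`traitenv` fits a hierarchical Bernoulli-logit model for species occurrence
in which functional traits modulate species' responses to environmental
gradients:

logit(p_ij) = α + a_j + (β₁ + b_j)·X_i + Σ_{t,e} β₁₂[t,e]·X_i[e]·Z_j[t] + c_i

with i = 1..n plots and j = 1..m species.  The species random vector
(a_j, b_j) is 4-dimensional (intercept plus one slope per environmental
variable) with covariance Σ; the site intercept c_i has SD σ_site.  Traits
appear only in the interaction term: the model's premise is that traits act
by shifting environmental responses, not by directly shifting prevalence.
With 3 environments and 4 traits the fixed-effect vector has
1 + 3 + 12 = 16 entries, reported in a fixed order (intercept; environment
main effects; trait × environment interactions, trait-major).

Estimation is approximate Bayesian maximum posterior ("MAP") estimation in
the penalized mixed-model family:

* priors — normal(0, 1) on every fixed effect; inverse-Wishart(df = 8,
  scale = 2·I₄) on Σ (mode Σ = 2I/13); inverse-gamma(shape 0.5, scale 100)
  on the site variance.  These are weak but proper, so complete separation
  and zero-presence species still yield finite estimates.
* random effects are integrated out by a Laplace approximation.  The inner
  problem (modes of all m·4 + n random effects given the parameters) is
  solved by a damped Newton iteration on the joint penalized log posterior;
  the Hessian is assembled exactly from its block structure (4 × 4 species
  blocks, diagonal site block, species-site couplings) and factorized
  densely — at the study scale (150 × 31) the system is only 274 × 274.
* the outer optimization runs L-BFGS-B with finite-difference gradients
  over the 16 fixed effects, the log-Cholesky parameters of Σ (10) and
  log σ_site, starting from zeros and identity covariances.  The fit is
  deterministic given the data.  Convergence is reported via the optimizer
  status and the final gradient norm; non-convergence sets a flag rather
  than raising.

Standard errors of the fixed effects are the inverse curvature of the
approximated log posterior at the mode: the Schur complement of the joint
negative Hessian over (fixed effects, random effects), with the variance
components held at their estimates — the convention of the penalized
mixed-model software family this method belongs to.  P-values are two-sided
Wald z tests with no degrees-of-freedom correction.

### Validation against numerical integration

An independent quadrature route (`traitenv.quadrature`) computes the
marginal likelihood by adaptive Gauss-Hermite integration, with its own
first-principles likelihood code, on instances without a site effect (where
species factorize).  On a seeded 2-species × 4-plot instance with a species
random intercept the Laplace marginal log likelihood agrees with 40-node
quadrature to better than 1% relative error for variances in [0.1, 2], and
the Laplace MAP of the fixed effects agrees with the quadrature MAP to
about 3·10⁻⁴.  The Laplace error grows with the random-effect variance and
dimension (at variance 2 with the full 4-dimensional species effect the log
marginal is off by about 2%) — the familiar behaviour of Laplace
approximations for sparse binary data.

## Preprocessing

* Aspect (compass degrees) is folded to a south-north orientation axis:
  values ≤ 180 pass through, values above become (360 − aspect); 0 = north-
  facing, 180 = south-facing.  Inputs of exactly 360 are treated as 0.
* Every other covariate and all four traits are natural-log transformed
  (raw distributions are strongly right-skewed; seed mass alone spans four
  orders of magnitude).  If zeros are present the offset is half the
  smallest positive observed value; the offset is recorded so the transform
  is invertible.  The log base and offset policy are package conventions,
  recorded per column.
* Each column is then centred and divided by twice its sample SD (n − 1
  denominator), giving mean 0 and SD 0.5.  On this scale the intercept is
  the prevalence at mean traits and mean environment, and coefficients of
  continuous predictors are comparable to those of binary ones.
* Environments are standardized over the plots of each fitted dataset
  (every 150-plot replicate defines its own "mean environment"); traits
  over the modelled species.  All statistics live in
  `StandardizationRecord`s written next to every fit, so any design can be
  rebuilt bit-for-bit from raw tables.

## Spatial subsampling

Each one-hectare set of 100 contiguous 10 m × 10 m plots is thinned by
laying a 3 × 3 grid over it and drawing 3 plots per cell without
replacement: 27 per set, plus all 69 scattered plots, is 150 plots per
modelling dataset.  Since 10 rows do not divide into 3 bands evenly, rows
and columns are partitioned 4/3/3 (cell sizes 16, 12, 12, 12, 9, 9, 12, 9,
9) — contiguous and as near-equal as possible; the partition is
configurable.  Replicate r uses seed base_seed + r, recorded in the output,
and replicate 1 is the one reported in detail (with cross-replicate ranges
alongside).  Moran's I on per-plot residuals checks that thinning removed
spatial autocorrelation.

## Evaluation

* AUROC: rank-based with mid-rank ties (Mann-Whitney form).  Because
  "AUROC across all species" is ambiguous, both the pooled value (all
  plot × species cells concatenated) and the per-species mean are computed;
  the pooled value is the default headline.
* AUPRC: average-precision summation, not trapezoidal interpolation
  (trapezoids overestimate PR area).  A random classifier's AUPRC equals
  prevalence, so AUPRC/prevalence is the fold improvement over random; it
  is reported per species with mean and min-max.
* Moran's I: computed on the per-plot mean Pearson residual across species
  using population-level (fixed-effects-only) predictions; deviance
  residuals and other aggregations are configurable.  Weights are inverse
  Euclidean distance, row-standardized, zero diagonal (k-nearest-neighbour
  binary weights available).  The p-value is a seeded 999-permutation test,
  two-sided around the null expectation −1/(N−1) by default.
* Conditional R²: latent-scale variance partition
  (σ²_fixed + σ²_random) / (σ²_fixed + σ²_random + π²/3), where σ²_fixed is
  the variance of the fixed-effect linear predictor over all cells and
  σ²_random = σ²_site + mean_i(X̃_iᵀ Σ X̃_i) (X̃ the species random-effect
  design).  The distribution-specific variance π²/3 is the standard-logistic
  choice.  Other R² conventions exist; this one is recorded and
  configurable in code.

## Synthetic communities

The generator reproduces the study's *structure*, not its geography: three
10 × 10 plot sets with 10 m spacing on distinct base elevations spread over
200–1000 m (within-set linear gradient plus smooth noise, so sets contrast
environmentally), 69 scattered plots uniform over the elevation range,
aspects uniform on [0, 360), slopes uniform on (1, 40) degrees.  Traits are
drawn log-uniformly inside the observed ranges (SLA 5.60–45.05, seed mass
0.10–9259 mg, wood density 0.35–0.85 g cm⁻³, maximum height 5–30 m) with
the endpoints pinned, so fixture extremes always match the configured
ranges — a fixture policy, not an estimate of any real community.
Occurrences are Bernoulli draws from the model above at configurable true
parameters; the defaults are the reference analysis' fitted point estimates
(α = −2.23; β₁ = 0.27, −0.15, 0.34; the 12 interactions; random SDs 1.32,
1.01, 0.70, 0.40, 0.42).  Species random-effect correlations default to 0
(no off-diagonal estimates are available to emulate); a full covariance can
be supplied.

What the generator does *not* emulate: dispersal or point-process spatial
clustering of occurrences beyond the site random effect, realistic terrain
(slope/aspect are independent of elevation), trait covariation between
species, or observation error.  Passing recovery tests therefore show that
the estimator recovers the data-generating parameters under the model's own
assumptions — they do not validate the model against ecological
misspecification.

For parameter-recovery experiments, `simulate_fit_dataset` standardizes the
design on exactly the 150 sampled plots and simulates from that design, so
the simulation truth lives on the same scale the fit estimates and recovery
can be judged exactly.

## Problem sizes and numerical tolerances

* Inner Newton: converges at gradient ∞-norm < 1e-9 (1e-12 step-halving
  line-search guard); outer L-BFGS-B: ftol 1e-12, projected-gradient
  tolerance 1e-5, finite-difference step 5e-7.  All exposed via `control`.
* A full 150 × 31 fit takes a few seconds on one CPU.  The shipped recovery
  experiments use 50 replicates in the test suite and 40 in the acceptance
  script — enough for Monte-Carlo SEs a few times smaller than the biases
  being tested — with 200-replicate runs available through the same API.
* Degenerate inputs: constant covariate columns raise a degenerate-input
  error; species with zero presences (or zero absences) are retained —
  the priors keep them finite — but flagged in fit diagnostics; single-class
  label vectors make AUROC/AUPRC undefined errors; constant residuals make
  Moran's I undefined.

## Known limitations

* The inverse-gamma(0.5, 100) site-variance prior is weak in its shape but
  its scale pulls the site variance upward in moderate samples: with 150
  sites the posterior-mode site SD sits noticeably above a true SD of ~1.3.
  This is a property of the stated prior, visible in the simulation
  experiments, and does not disturb the fixed-effect recovery; the prior is
  configurable.
* Laplace integration of binary-data random effects carries a known small
  bias for large random-effect variances; the quadrature oracle bounds it
  on small instances but cannot be run at the full crossed design.
* P-values are Wald z tests; no finite-sample degrees-of-freedom
  correction is attempted.
* No full MCMC posterior, no model comparison, no phylogenetic random
  effects, and no spatially explicit occurrence mechanisms (autocovariate
  or CAR terms) — the site intercept plus subsampling design is the only
  spatial treatment, mirroring the analysis this package implements.
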