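# Methods

This note documents the models implemented in `eivsdm`, the inference
machinery behind them, the synthetic-data generator used to study them,
and the numerical choices that were genuinely open.

## The problem

A species distribution model (SDM) relates presence/absence records
y(sᵢ) ∈ {0, 1} at field-visit locations sᵢ to environmental ("abiotic")
covariates.  In practice the covariates are measured (a) at *different*
locations aᵢ than the field visits — spatial misalignment — and (b)
with measurement error.  Using interpolated point estimates as if they
were exact is the standard two-stage practice; treating the covariate
fields as latent random variables inside one hierarchical model is the
errors-in-variables alternative.  The package implements both, plus the
naïve direct regression, and the simulation machinery to compare them
against known ground truth.

## Model components

**Covariate fields (kriging).**  Each uncertain covariate j is a latent
Gaussian random field X_j with mean α_j and Matérn covariance of
smoothness ν = 1,

  C(d) = σ² (κd) K₁(κd),   κ = √8 / r,

so that the *range* r is the distance at which correlation falls to
≈ 0.14.  Observations are classical-error contaminated:
x*_j(aᵢ) = X_j(aᵢ) + ε, ε ~ N(0, δ²_j).  Priors: α ~ N(0, 1000),
log σ², log r ~ N(0, 10), and a Gamma(1, 10⁻⁵) prior on the precision
1/δ².  The N(0, 10) scale is read as a variance; these priors are vague
by design and the defaults of the `PriorConfig` dataclass.

**SDM (logistic GAMM).**  y(sᵢ) ~ Bernoulli(μᵢ), logit(μᵢ) = ηᵢ with

  ηᵢ = β₀ + Σⱼ βⱼ xⱼ(sᵢ) + Σⱼ fⱼ(zⱼ(sᵢ)) + W(sᵢ).

Linear coefficients get N(0, 1000) priors.  Each fⱼ is a random-walk-2
spline over d equal-width bins of its covariate (default d = 20):
second differences of the bin values are iid N(0, ζ²), 1/ζ² ~
Gamma(1, 10⁻⁵).  W is a Matérn (ν = 1) spatial residual with its own
(σ₀², r₀) and the same vague hyperpriors.

**Three estimators.**
*Direct*: fit the GAMM to covariate values observed at the field-visit
locations, taken at face value.  Only possible for aligned data; under
measurement error the coefficients attenuate (regression dilution — the
linear-Gaussian analogue (Σ_X + δ²I)⁻¹ Σ_X β is exposed as
`attenuation_oracle` for sanity bounds).
*Two-stage*: fit one kriging model per covariate, plug the posterior
means x̂ⱼ(sᵢ) into the GAMM as known constants.  Kriging means are
smoother than the truth (Berkson-type error), so prediction is largely
protected but the covariate uncertainty is discarded.
*Joint*: one posterior over all K kriging models and the GAMM, with
latent covariate values at the field-visit locations feeding η as
random variables.  Information flows both ways: species data inform the
covariate fields (feedback can be cut with
`InferenceConfig(feedback=False)` for sensitivity analysis).

## Inference

**Kriging hyperparameters.**  With the latent field integrated out
analytically, the 4-dimensional posterior p(α, log σ², log r, log δ² |
x*) is handled either by a Laplace approximation at its mode (default)
or by emcee ensemble MCMC with split-R̂ / effective-sample-size
diagnostics (convergence declared at R̂ < 1.05, ESS > 200; failures are
flagged, never silent).  At sparse designs (M ≈ 100) this likelihood is
often bimodal — a short-range/low-nugget regime versus a
long-range/high-nugget one — so the Laplace mode search is multi-start
(three starts covering both regimes plus a moment-based middle).  The
MCMC engine explores both modes and the full heavy σ² tail; the Laplace
engine reports the dominant mode with light tails, which is the
behaviour of standard mode-centred kriging software and is what the
two-stage and joint fitters use for stage 1.  Latent values anywhere
are reconstructed per hyperparameter draw through exact Gaussian
conditioning (`gp_conditional`), and posterior summaries are mixture
summaries over draws — the package never summarizes a nonlinear
function of a draw by transforming a summary.

**Logistic models.**  All three fitters share a Pólya-Gamma Gibbs
sampler: ω_i ~ PG(1, η_i) makes every Gaussian block conditionally
conjugate.  PG(1, z) variates are drawn from the truncated infinite
gamma-mixture series (100 terms) with the exact mean of the dropped
tail added back; the residual error is far below Gibbs Monte-Carlo
noise.  Design choices that matter for correctness, mixing and cost:

- (β, W) are sampled as *one* Gaussian block.  Spatially structured
  covariates are partially confounded with W, and separate updates mix
  an order of magnitude more slowly.
- In the joint model the coefficients additionally move through a
  *marginal* Metropolis kernel: every other sweep, β is updated against
  its collapsed target with all latent covariate fields and W
  integrated out analytically (everything is Gaussian given ω), after
  which the latents are redrawn exactly from their joint conditional by
  Matheron's conditioning rule (prior draw plus gain correction).
  Without this kernel the β/latent-field ridge keeps effective sample
  sizes in the tens and chains can stick in regimes for entire runs.
- Covariate-field hyperparameters in the joint model follow a "cut"
  schedule by default: the sampler runs in segments (default 6), each
  conditioned on one draw from the stage-1 kriging posterior, with a
  short re-equilibration discard at each switch.  This propagates
  stage-1 hyperparameter uncertainty multiple-imputation style; species
  data feed back into the latent field *values* but not into the field
  hyperparameters.  Fully sampled hyperparameters remain available
  (``field_hypers="sample"``) together with collapsed Metropolis moves
  that integrate the field out, but they sit on the same ridge and need
  far longer chains.
- The spatial residual's (σ₀², r₀) get both conditional updates and
  collapsed moves (W integrated out of the pseudo-Gaussian model) in
  the joint sampler.
- Matérn ranges inside the Gibbs samplers move on a data-driven
  log-spaced grid (default 16 values spanning 0.05–2× the data extent)
  whose correlation inverses and log-determinants are precomputed once
  per point set.  The W grid is additionally floored at 3× the median
  nearest-neighbour spacing: a residual with range below the data's
  resolution degenerates into a free per-point logit that can separate
  binary data.  The continuous treatment is retained in the kriging
  module, and the two engines are cross-checked in the tests.
- η is clipped to |η| ≤ 10 inside the augmentation draw (probabilities
  within 5·10⁻⁵ of 0/1).  Unbounded η lets weakly identified fits drift
  into a saturated absorbing state (ω → 0, pseudo-data → ±∞).
- Field variances use an independence-Metropolis step whose proposal is
  the exact inverse-gamma conditional under a flat prior, so the
  acceptance ratio only involves the log-normal prior (acceptance near
  1).
- RW2 splines are sampled under a sum-to-zero constraint (conditioning
  by kriging), which keeps the intercept identifiable; the constraint
  is recorded in the fit diagnostics.  W is left unconstrained — its
  prior mean 0 suffices at the sample sizes used here.

Convergence of the Gibbs fits is summarized by split-R̂ and ESS of the
first linear coefficient (with an allowance under the cut schedule,
whose between-segment variance is real posterior spread); `max_seconds`
lets long joint fits stop early with an explicit `truncated` flag and a
warning rather than silently.

**Prediction.**  Occurrence maps are computed draw-wise: per posterior
draw, latent fields and W are conditionally simulated at the grid cell
centres (cell centre = origin + (i + ½)·size), η assembled, and
probabilities averaged on the μ scale.  Covariance factors are cached
per distinct range-grid value, which makes the per-draw cost a
matrix-vector product.

## The synthetic-data generator

`generate_dataset` draws everything on the unit square, mirroring the
study conditions it emulates: N = 1000 field-visit and M = 100
measurement locations sampled uniformly (misaligned mode); three
independent Matérn fields Z, Z₁, Z₂ with σ²† = 0.5, r† = 0.3 build
confounded covariates X₁ = Z + Z₁, X₂ = Z + Z₂ (ensemble Var = 1,
Cov = 0.5); classical measurement error with δ²† = 0.3; and
η = −2 + X₁ + X₂ + W with an independent Matérn W (same σ²†, r†) —
implying ≈ 20% prevalence.  Aligned mode measures the abiotics at the
field-visit locations plus M extra points.  The truth (latent fields,
η, μ on the observation points and a 25×25 evaluation grid) is retained
for scoring only; estimators receive nothing but observed tables, and a
test asserts this.

What the generator does *not* emulate: real surveys are stratified
rather than uniform, covariates are neither Gaussian nor
variance-standardized by nature, measurement error need not be
homoscedastic or Gaussian, and real species respond nonlinearly.
Passing the simulation study therefore shows that each estimator
recovers the generative parameters *of this model class* under
misalignment and noise — not that the model class fits any particular
survey.

## Numerical choices

- Covariances are dense; a jitter of 10⁻⁸·σ² is added to diagonals
  before factorization, and a factorization failure raises with the
  smallest eigenvalue in the message.
- Hot likelihood paths evaluate the ν = 1 Matérn correlation from a
  120 000-point tabulation of u·K₁(u) (absolute error ≤ ~3·10⁻⁷, an
  order of magnitude below any tolerance in use); the public
  `matern_correlation` stays exact Bessel and anchors the oracle tests.
- Hyperparameter draws on the log scale are clipped to ±25 before
  exponentiation so a diffuse Laplace approximation cannot underflow to
  an exactly-zero variance.
- Distances are Euclidean in the units supplied; no geodesy.
- Duplicated observation locations are allowed and are what identifies
  δ² without spatial extrapolation.
- Degenerate inputs fail loudly: constant covariates cannot carry a
  spline, empty grids and empty point tables are errors, constant maps
  make Pearson correlations "undefined" rather than NaN.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; study summaries are bit-reproducible
  given (config, seed).

## Problem sizes in the shipped study scripts

`scripts/acceptance.py` runs the misaligned setting at the full study
scale (N = 1000, M = 100), because posterior-sd comparisons are
design-dependent, and the aligned settings — which enter only through
run-averaged posterior means, which do not depend on N in expectation —
at N = 400 (N = 800 for the regression-dilution average, where the
small-sample inflation of logistic coefficients is no longer
negligible).  Run counts (5–7 per setting; 12 for the cheap direct
fits) keep the Monte-Carlo error of each run average a fraction of the
per-run spread (≈ 0.2–0.4).  The test suite uses still smaller
instances with tolerances widened by the corresponding a-priori
Monte-Carlo standard errors, stated in each test.

## Known limitations

- The range-grid discretization caps how finely the spatial range
  posterior is resolved; with very informative data the grid resolution
  (16 points over 1.6 decades) becomes the limiting factor.
- At M ≈ 100 measurement locations the kriging-model hyperparameters
  are only weakly identified; occasional simulation replicates produce
  strongly shrunken covariate predictions on which every estimator —
  including a fit given the true covariate values — lands far from the
  generative coefficient.  Run-averaged summaries at a handful of
  replicates are visibly sensitive to such draws.
- The joint model's default "cut" treatment of field hyperparameters
  does not let species data revise them (the latent field values do
  receive feedback); the fully sampled alternative needs much longer
  chains to traverse the hyperparameter/coefficient ridge.
- Splines of *uncertain* covariates are not supported (uncertain
  covariates enter linearly), matching the scope of the estimators
  compared here.
- No anisotropy, no non-Gaussian measurement error, no temporal
  misalignment.
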