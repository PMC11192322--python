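# eivsdm

Species distribution modelling when the environment is measured in the
wrong places, with error.

Presence/absence surveys record a species at field-visit locations
**s**; abiotic covariates (soil chemistry, pH, …) are measured at other
locations **a** (spatial misalignment) and carry measurement error.
The common practice — interpolate each covariate, plug the interpolated
values into a regression as if exact — discards the covariate
uncertainty.  `eivsdm` implements that two-stage approach and a joint
hierarchical errors-in-variables alternative side by side, plus the
ground-truth simulation machinery to compare them:

- **Kriging** of each covariate j: latent Matérn (ν = 1) Gaussian field
  X_j with mean α_j, variance σ²_j, range r_j; observations
  x*_j(a) = X_j(a) + ε, ε ~ N(0, δ²_j).
- **SDM**: Bayesian logistic GAMM,
  y(sᵢ) ~ Bernoulli(μᵢ), logit(μᵢ) = β₀ + Σⱼ βⱼ xⱼ(sᵢ) + Σⱼ fⱼ(zⱼ(sᵢ)) + W(sᵢ),
  with RW2 splines fⱼ and a Matérn spatial residual W.
- **Three estimators**: `fit_direct` (observed values taken as truth —
  attenuates under error), `fit_two_stage` (kriging posterior means as
  plug-in constants), `fit_joint` (latent covariates inside one
  posterior; uncertainty propagates, information flows both ways).
- **Validation**: leave-region-out spatial cross-validation, Brier-root
  RMSE, and regional prevalence prediction intervals.
- **Simulation study**: confounded Gaussian-field covariates
  (Var = 1, Cov = 0.5), switchable misalignment and measurement error,
  known effects (β₀, β₁, β₂) = (−2, 1, 1), and an S4-style summary
  table over replicate runs.

Inference is exact-likelihood Bayesian throughout: a Laplace or emcee
treatment of the 4-parameter kriging posteriors, and a Pólya-Gamma
Gibbs sampler for the logistic hierarchy.  See `docs/methods.md` for
the full model and sampler description.

## Worked example

Simulate one misaligned, error-contaminated dataset at desk scale and
compare the two-stage and joint fits:

```python
import numpy as np
from eivsdm import (SimulationConfig, generate_dataset, SdmSpec,
                    InferenceConfig, fit_two_stage, fit_joint)

config = SimulationConfig(n_species=500, n_abiotic=100)   # unit square
data = generate_dataset(config, run_seed=7)
spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
inference = InferenceConfig(n_warmup=250, n_draws=550, seed=1)

two = fit_two_stage(data.species, data.abiotic, spec, inference=inference)
joint = fit_joint(data.species, data.abiotic, spec, inference=inference)
print(two.coef_summary.round(3))
print(joint.coef_summary.round(3))
```

```
            mean     sd   q2.5  q97.5
intercept -1.838  0.513 -2.933 -0.970
x1         1.291  0.407  0.503  2.102
x2         1.137  0.447  0.276  2.030
            mean     sd   q2.5  q97.5
intercept -2.029  0.361 -2.693 -1.325
x1         1.589  0.558  0.678  2.858
x2         1.120  0.442  0.313  2.011
```

The true effects are β₁ = β₂ = 1 with intercept −2: at M = 100 noisy
measurements both models' intervals cover the truth, and single runs
carry posterior sds of ~0.4–0.6 at this reduced N.  Averaged over
replicate datasets (see the study below) both estimators recover the
effects, while the naïve direct regression on error-contaminated values
attenuates toward zero (regression dilution).

The same comparison from the shell:

```sh
eivsdm simulate --kind misaligned --size tiny --seed 3 --out data/
eivsdm study --models two_stage,joint --runs 5 --seed 3 --out study.csv
```

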