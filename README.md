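# depgp

Spike-and-slab Gaussian process regression for inferring **sample-specific
protein (kinase) dependencies** from high-throughput drug screens.

Chemical-perturbation experiments measure how strongly each of *D* drugs
inhibits each of *S* tumour samples (a drug × sample sensitivity matrix
**Y**), while affinity profiling measures how strongly each drug binds each
of *P* candidate proteins (a drug × protein matrix **X**).  Because most
drugs are polypharmacological, the response of a sample to a drug mixes the
effects of every protein the drug binds.  `depgp` deconvolves these signals:
it infers *which* proteins the responses depend on — with posterior
probabilities, not just a point estimate — and *how* (possibly nonlinearly)
each protein's binding strength maps to the response.

## Model

For drug *d* and sample *s*,

```
Y_ds = α_s + Σ_p z_p · 1(X_dp observed) · f_ps(X_dp) + ε_ds,   ε_ds ~ N(0, σ²)
```

* `z_p ~ Bernoulli(π₀)` — a spike-and-slab indicator that switches protein
  *p*'s entire contribution in or out (default π₀ = 0.1),
* `f_ps ~ GP(0, k⁰_ν)` — a per-(protein, sample) contribution curve with a
  Gaussian-RBF kernel **conditioned on f(0) = 0**: a drug that does not bind
  a protein (affinity 0) cannot act through it,

  ```
  k⁰_ν(x₁,x₂) = ν₁ [ exp(−(x₁−x₂)²/2ν₂²) − exp(−(x₁²+x₂²)/2ν₂²) ]
  ```
* `α_s | γ² ~ N(0, γ²)`, `γ² ~ Half-Normal(0,1)`, `σ² ~ Inv-Gamma(a₀,b₀)`
  with a₀ = b₀ = 1.

**Missing data need no imputation.**  A missing affinity X_dp contributes
exactly zero to the mean; missing responses are dropped from the likelihood.
Integrating out α and every f analytically gives the per-sample marginal

```
Y_obs,s ~ N(0, γ²J + σ²I + Σ_p z_p K̄⁽ᵖ⁾)
```

with K̄⁽ᵖ⁾ the missingness-masked constrained kernel matrix of protein
column *p*.  A two-block MCMC sampler alternates Metropolis–Hastings moves
on (Z, σ², γ²) against this marginal with Bayesian-backfitting Gibbs draws
of the intercepts and curves.  Proteins with posterior inclusion
probability above 0.95 are reported as dependencies.  A linear variant
(`f_ps(x) = β_ps·x`, the kernel ν₁·x₁·x₂) is included as a faster baseline,
and kernel parameters ν = (ν₁, ν₂) are chosen by 3-fold cross-validated
grid search on normalized MSE.

## Worked example

```python
import numpy as np
from depgp import (HyperParams, KernelParams, SamplerConfig, ScenarioConfig,
                   gelman_rubin, generate, inclusion_probabilities, nmse,
                   posterior_predict, run_mcmc, select_proteins)

data = generate(ScenarioConfig(seed=0))          # 30 drugs x 8 proteins x 5 samples
hp = HyperParams(kernel=KernelParams(0.155, 0.126))
samples = run_mcmc(data.X, data.Y, hp, SamplerConfig(seed=0))

pip = inclusion_probabilities(samples)
for name, prob, z in zip(data.X.protein_ids, pip, data.truth.Z):
    print(f"{name}  PIP={prob:5.3f}  truly_active={bool(z)}")
print("selected:", sorted(select_proteins(samples)))
yhat = posterior_predict(samples, data.X)
y_obs = np.where(data.Y.observed, data.Y.values, np.nan)
print(f"in-sample nMSE: {nmse(y_obs, yhat):.3f}")
print(f"R-hat sigma^2: {gelman_rubin(samples, 'sigma2'):.3f}, "
      f"gamma^2: {gelman_rubin(samples, 'gamma2'):.3f}")
```

prints

```
protein_00  PIP=0.000  truly_active=False
protein_01  PIP=0.000  truly_active=False
protein_02  PIP=1.000  truly_active=True
protein_03  PIP=0.000  truly_active=False
protein_04  PIP=0.000  truly_active=False
protein_05  PIP=1.000  truly_active=True
protein_06  PIP=0.000  truly_active=False
protein_07  PIP=0.000  truly_active=False
selected: ['protein_02', 'protein_05']
in-sample nMSE: 0.102
R-hat sigma^2: 1.031, gamma^2: 1.018
```

The two truly informative proteins are recovered with posterior inclusion
probability 1.0, the six decoys are excluded, the posterior-mean prediction
explains ~90% of the response variance, and the six chains agree (R̂ well
below the 1.1 convergence bound).

The same workflow is available from the shell:

```bash
depgp simulate --preset default --seed 0 --out sim/
depgp fit --affinity sim/X.csv --sensitivity sim/Y.csv \
          --transform none --model gp --seed 0 --out run/
depgp cv  --affinity sim/X.csv --sensitivity sim/Y.csv \
          --nu1-grid 0.0825,0.155 --nu2-grid 0.126,0.3 --seed 0 --out cvrun/
```

`fit` writes inclusion probabilities (TSV), the selected-protein list, the
posterior-mean response matrix (CSV), posterior-mean contribution curves
for selected proteins, trace/R̂ summaries and a JSON run manifest.  Real
datasets should be preprocessed with `--transform logit` (raw viabilities
in (0,1)) or `--transform log` (positive responses); boundary values are
hard errors unless `--clip-eps` is given.

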