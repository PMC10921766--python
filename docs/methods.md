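# Methods

## Model

`depgp` models a drug × sample sensitivity matrix **Y** (S tumour samples
screened against D drugs) as an additive function of a drug × protein
affinity matrix **X** (D drugs profiled against P candidate proteins):

    Y_ds = α_s + Σ_p z_p · 1(X_dp observed) · f_ps(X_dp) + ε_ds

- **Selection.** z_p ~ Bernoulli(π₀) gates protein p's contribution for
  *all* drugs and samples at once, mirroring a group penalty but yielding a
  posterior inclusion probability (PIP) instead of a point estimate.
- **Contribution curves.** f_ps ~ GP(0, k⁰_ν) with the Gaussian-RBF kernel
  conditioned on f(0) = 0 (k⁰ is the Schur complement of the origin).  The
  constraint encodes that a drug with zero affinity does not act through
  that protein; it also anchors each curve, removing the translation
  degeneracy between curves and the intercept.
- **Noise and intercepts.** ε_ds ~ N(0, σ²) with σ² ~ Inv-Gamma(a₀, b₀);
  α_s ~ N(0, γ²) with γ² ~ Half-Normal(0, 1) — the half-normal is placed on
  the *variance* γ² itself, read literally from the model definition.

### Missing data

Missingness is structural, not imputed.  Missing affinities zero out the
corresponding kernel rows/columns (matrix K̄⁽ᵖ⁾); missing responses are
dropped from the likelihood, which factorizes over sample columns.  With α
and all f integrated out analytically the observed responses of sample s
are jointly Gaussian:

    Y_{-M_s} ~ N(0, Σ̄_s),  Σ̄_s = γ²J + σ²I + Σ_p z_p K̄⁽ᵖ⁾ (observed rows)

This marginal is the target of the structure-level sampler, so selection
moves never depend on the current curve values.

## Posterior inference

Each MCMC iteration has two blocks:

1. **Structure (marginalized MH).**  A sweep of single-flip proposals over
   the z_p in random order (symmetric, so the acceptance ratio is the
   marginal-posterior ratio), followed by log-scale Gaussian random walks
   on σ² and γ² with the log-Jacobian in the ratio.
2. **Backfitting (exact Gibbs).**  For each sample: the intercept α_s from
   its conjugate-normal conditional given the partial residual, then each
   active f_ps jointly at all of its column's present design points from
   the exact GP conditional.  Inactive curves are refreshed from the GP
   prior so activation proposals always have well-defined values; because
   block 1 is marginalized this does not disturb its target.

Protocol defaults: 6 chains × 120 iterations, burn-in 20 (100 retained per
chain), independent initializations z_p ~ Bernoulli(π₀), σ² = γ² = 1,
α = 0, f = 0, all streams spawned from one seed.  Convergence is reported
(not enforced) via the classical multi-chain Gelman–Rubin PSRF of σ² and
γ² on the retained draws, against the conventional 1.1 bound; the plain
(non-split) form is used because 100 retained draws per chain is too short
for split-R̂ refinements.

### Tunable parameters

| parameter | default | role |
|---|---|---|
| ν₁ | 0.155 | kernel amplitude ≈ prior variance of each curve (response units²) |
| ν₂ | 0.126 | kernel length-scale on the affinity axis (affinity units; data scaled to (0,1)) |
| π₀ | 0.1 | prior inclusion probability — a-priori sparsity of ~P·π₀ active proteins |
| a₀, b₀ | 1, 1 | Inv-Gamma noise-variance prior (heavy-tailed, weakly informative) |
| proposal scales | 0.5 (σ²), 1.0 (γ²) | log-RW step sizes |
| selection threshold | 0.95 | report proteins with PIP strictly > 0.95 |

The fit is driven primarily by ν; the defaults sit mid-grid of the 5 × 6
CV grid (ν₁ ∈ {0.01, 0.0825, 0.155, 0.2275, 0.3}, ν₂ ∈ {0.01, 0.068,
0.126, 0.184, 0.242, 0.3}), whose scale presumes affinity scores in
roughly (0, 1) — rescale consciously before fitting other ranges.

The MH proposal scales were set by standard acceptance-rate tuning on
simulated data: γ² is informed by only S intercepts, so its posterior stays
nearly as broad as its prior and a narrow random walk (acceptance ≈ 0.9)
mixes poorly; the defaults give acceptance rates ≈ 0.3–0.7.  Both scales
remain user-settable.

### Cross-validation

`cross_validate` partitions the *observed (d, s) cells* at random into
k = 3 folds (cell-wise, not drug-wise: holding out cells exercises exactly
the missing-response machinery the model is built on), marks held-out
cells missing, refits, predicts them from the posterior mean, and scores
normalized MSE ‖Y−Ŷ‖²/‖Y−Ȳ‖² on the held-out cells.  nMSE is evaluated on
the model (transformed) scale.  The best ν is the grid argmin, ties broken
toward the smallest ν₁ then ν₂ (smoother models).  Selected-protein sets
can be compared across grid points or against an external reference with
IoU; IoU(∅, ∅) := 1 (identical sets).

## Synthetic data

The generator draws from the generative model itself: affinities uniform
on (0, 1) masked at rate 0.6 (the ~0.9 missingness of real kinobead-type
screens makes desk-scale columns unidentifiable; the `paper_like` preset
uses 0.9 at D = 120), exactly `n_active` informative proteins, curves
either drawn from the constrained-kernel GP (`gp_draw`), set to
non-monotonic cap shapes c·x(1−x) with |c| ∈ [2, 4] (`cap_shape`), or
linear (`linear`), noise σ² = 0.05, intercept spread γ² = 0.25, responses
masked at rate 0.1 (never below 2 observed per column).  Defaults:
D = 30, P = 8, S = 5, 2 active proteins.

What passing tests on these data do **not** show: real affinity matrices
have correlated missingness (panel design, not uniform), batch structure,
and measurement error in X itself, none of which the generator emulates;
effect sizes are also homogeneous across active proteins, whereas real
dependencies vary widely.  Under `gp_draw` a drawn curve can by chance be
small relative to the noise, in which case the *exact* posterior itself —
not merely the sampler — correctly declines to include that protein;
recovery claims therefore describe typical draws, not a guarantee for
every realization.

## Numerical choices

- Any Gram or marginal covariance matrix that is factorized gets diagonal
  jitter 1e-6·ν₁ (duplicate design points otherwise make it singular).
  Duplicated affinity values are kept, relying on the jitter.
- Design points with affinity exactly 0 are valid input ("drug does not
  bind"): their kernel rows vanish, so the curve value is pinned to
  exactly 0 there and excluded from factorized blocks — GP paths honour
  f(0) = 0 to machine precision rather than jitter precision.
- Protein columns with no observed affinity are dropped at load time with
  a warning: their kernel matrix is zero and z_p would just sample its
  prior.
- Boundary responses (0/1 under logit, ≤0 under log) are hard errors; the
  `clip_eps` opt-in clips into [ε, 1−ε].  z-scores use the sample (n−1)
  standard deviation.
- Cholesky failures after jitter are raised with iteration context, not
  silently retried.

## Design choices where the design was open

- **Curve representation.**  f_ps is stored by its values at its column's
  present design points (the GP's finite-dimensional marginal); values
  elsewhere come from the GP conditional mean.  Sufficient for the
  likelihood, prediction and plotting.
- **Update order.**  Structure block first, then backfitting, sweeping
  samples in index order; fixed for reproducibility (any order is valid).
- **Linear variant prior.**  β_ps ~ N(0, τ²) with τ² ~ Half-Normal(0, 1)
  sampled in the structure block — the natural analog of the GP amplitude;
  τ² handling is configurable (fixable, re-scalable).
- **Selection pooling.**  PIPs pool retained draws across chains; the
  >95% rule is applied to the pooled frequency.
- **Cell-wise CV folds** (see above) with the fold seed recorded in every
  output manifest.

## Problem sizes

Tests and the acceptance script run the full 6 × 120 protocol at the
default scenario size (30 × 8 × 5; seconds per fit on one core).  The MC
marginalization oracle uses 1e5 prior draws on D = 6, P = 2, S = 2
instances; enumeration checks use P = 2 (4 structures).  These sizes were
chosen so every check reruns comfortably on a laptop; the model itself has
no intrinsic size limit beyond O(Σ_s n_s³) per likelihood evaluation.

## Known limitations

- The sampler is exact but single-flip MH over Z can mix slowly between
  well-separated modes (e.g. two highly correlated protein columns); the
  6-chain protocol with R̂ reporting is the guard, not a cure.
- γ² and σ² random walks are untempered; extremely informative data with
  tiny σ² may warrant smaller proposal scales.
- nMSE comparisons across response transforms are normalized but still
  scale-dependent in the tails; back-transformed-scale evaluation is not
  implemented.
- No multi-kernel or per-protein ν: one (ν₁, ν₂) is shared by all curves,
  matching the single-ν grid search.
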