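"""Two-block MCMC for the spike-and-slab GP model, plus posterior summaries.

Each iteration alternates:

1. a Metropolis-Hastings sweep on the *structure* block (Z, sigma^2,
   gamma^2) targeting the marginalized posterior — alpha and every f_ps are
   integrated out exactly, so these moves do not depend on the current
   function values;
2. a Bayesian-backfitting sweep drawing, for each sample s, the intercept
   alpha_s and every active contribution curve f_ps from their exact
   Gaussian full conditionals given the partial residuals of the other
   components.  Inactive curves (z_p = 0) are refreshed from the GP prior
   so that activation proposals always find well-defined function values;
   because the structure block is marginalized this does not perturb its
   target.

Structure proposals are single-coordinate z-flips (symmetric) in random
order followed by log-scale Gaussian random walks on sigma^2 and gamma^2
with the log-Jacobian included in the acceptance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core_model import (
    AffinityMatrix,
    HyperParams,
    LatentState,
    MarginalPrecomp,
    SensitivityMatrix,
    log_marginal_likelihood,
    log_structure_prior,
    mean_matrix,
)
from .kernels import DEFAULT_JITTER, constrained_kernel

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "BackfitCache",
    "backfit_update",
    "mh_update_structure",
    "run_mcmc",
    "inclusion_probabilities",
    "select_proteins",
    "posterior_predict",
    "posterior_mean_curves",
    "gelman_rubin",
    "trace",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC protocol settings.

    The defaults reproduce the reference protocol: chain length 120 with the
    first 20 iterations discarded as burn-in, and 6 independently
    initialized chains.
    """

    n_iter: int = 120
    burn_in: int = 20
    n_chains: int = 6
    seed: int = 0
    proposal_scale_sigma2: float = 0.5
    proposal_scale_gamma2: float = 1.0
    update_sigma2: bool = True
    update_gamma2: bool = True
    sigma2_init: float = 1.0
    gamma2_init: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.proposal_scale_sigma2 <= 0 or self.proposal_scale_gamma2 <= 0:
            raise ValueError("proposal scales must be positive")


@dataclass
class PosteriorSamples:
    """Retained post-burn-in states of one or more chains."""

    chains: list[list[LatentState]]
    log_posterior: list[np.ndarray]
    acceptance_rates: dict[str, float]
    config: SamplerConfig
    hp: HyperParams
    protein_ids: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_retained(self) -> int:
        return len(self.chains[0]) if self.chains else 0

    @property
    def states(self) -> list[LatentState]:
        """All retained states pooled across chains, chain-major order."""
        return [st for chain in self.chains for st in chain]


# ---------------------------------------------------------------------------
# backfitting block (Gaussian full conditionals)
# ---------------------------------------------------------------------------


class BackfitCache:
    """Per-protein design-point geometry and prior Cholesky factors.

    For protein p: ``idx[p]`` are the drug rows with observed affinity,
    ``nz[p]`` flags which of those have affinity != 0 (points at exactly 0
    carry f = 0 surely and are excluded from the Gaussian), ``chol[p]`` is
    the lower Cholesky factor of the constrained Gram matrix on the nonzero
    points plus jitter, and ``prior_cov[p]`` the jittered Gram itself.
    """

    def __init__(self, X: AffinityMatrix, params, kernel=constrained_kernel,
                 jitter: float = DEFAULT_JITTER) -> None:
        self.params = params
        self.kernel = kernel
        self.idx: list[np.ndarray] = []
        self.nz: list[np.ndarray] = []
        self.x_nz: list[np.ndarray] = []
        self.chol: list[np.ndarray | None] = []
        self.prior_inv: list[np.ndarray | None] = []
        for p in range(X.n_proteins):
            idx = X.present_indices(p)
            x = X.values[idx, p]
            nz = np.flatnonzero(x != 0.0)
            self.idx.append(idx)
            self.nz.append(nz)
            self.x_nz.append(x[nz])
            if nz.size:
                K = kernel(x[nz][:, None], x[nz][None, :], params)
                K = K + jitter * params.nu1 * np.eye(nz.size)
                L = linalg.cholesky(K, lower=True)
                self.chol.append(L)
                Linv = linalg.solve_triangular(L, np.eye(nz.size), lower=True)
                self.prior_inv.append(Linv.T @ Linv)
            else:
                self.chol.append(None)
                self.prior_inv.append(None)

    def prior_draw(self, p: int, rng: np.random.Generator) -> np.ndarray:
        """Draw f_p at all present design points from the GP prior."""
        n = self.idx[p].size
        f = np.zeros(n)
        L = self.chol[p]
        if L is not None:
            f[self.nz[p]] = L @ rng.standard_normal(self.nz[p].size)
        return f


def _draw_alpha(y_resid: np.ndarray, sigma2: float, gamma2: float,
                rng: np.random.Generator) -> float:
    """Conjugate draw of alpha_s given residuals of the other components.

    Posterior is N(n ybar / (n + sigma^2/gamma^2), (1/gamma^2 + n/sigma^2)^-1).
    """
    n = y_resid.size
    prec = 1.0 / gamma2 + n / sigma2
    mean = (y_resid.sum() / sigma2) / prec
    return float(mean + rng.standard_normal() / np.sqrt(prec))


def _draw_f(cache: BackfitCache, p: int, obs_pos: np.ndarray,
            resid: np.ndarray, sigma2: float,
            rng: np.random.Generator) -> np.ndarray:
    """Joint Gaussian draw of f_p at all present design points of column p.

    ``obs_pos`` indexes (into the present-point order) the design points
    whose drug has an observed response; ``resid`` are the corresponding
    partial residuals.  Points with affinity exactly 0 stay at f = 0.
    """
    n = cache.idx[p].size
    f = np.zeros(n)
    nz = cache.nz[p]
    if nz.size == 0:
        return f
    # positions within the nonzero subvector that are informed by data
    pos_map = -np.ones(n, dtype=int)
    pos_map[nz] = np.arange(nz.size)
    obs_nz = pos_map[obs_pos]
    keep = obs_nz >= 0
    obs_nz = obs_nz[keep]
    r = resid[keep]
    A = cache.prior_inv[p].copy()
    b = np.zeros(nz.size)
    if obs_nz.size:
        A[obs_nz, obs_nz] += 1.0 / sigma2
        np.add.at(b, obs_nz, r / sigma2)
    L = linalg.cholesky(A, lower=True)
    mean = linalg.cho_solve((L, True), b)
    z = rng.standard_normal(nz.size)
    f[nz] = mean + linalg.solve_triangular(L.T, z, lower=False)
    return f


def backfit_update(
    state: LatentState,
    s: int,
    X: AffinityMatrix,
    Y: SensitivityMatrix,
    hp: HyperParams,
    rng: np.random.Generator,
    cache: BackfitCache | None = None,
) -> LatentState:
    """One backfitting sweep for sample s; returns an updated copy.

    Redraws alpha_s and each f_ps: active curves from their exact Gaussian
    full conditional given the partial residuals, inactive curves from the
    GP prior.  A full sweep leaves the per-sample conditional posterior
    invariant.
    """
    if cache is None:
        cache = BackfitCache(X, hp.kernel)
    state = state.copy()
    obs = Y.observed_indices(s)
    y = Y.values[obs, s]
    P = X.n_proteins

    # current contribution of each active protein at the observed rows
    def contrib(p: int) -> np.ndarray:
        pos = np.searchsorted(cache.idx[p], obs)
        hit = (pos < cache.idx[p].size)
        hit[hit] = cache.idx[p][pos[hit]] == obs[hit]
        out = np.zeros(obs.size)
        out[hit] = state.f_values[p][pos[hit], s]
        return out

    active = [p for p in range(P) if state.Z[p]]
    total = np.zeros(obs.size)
    for p in active:
        total += contrib(p)

    # intercept
    resid_alpha = y - total
    state.alpha[s] = _draw_alpha(resid_alpha, state.sigma2, state.gamma2, rng)

    # contribution curves
    for p in range(P):
        if state.Z[p]:
            old = contrib(p)
            pos = np.searchsorted(cache.idx[p], obs)
            hit = (pos < cache.idx[p].size)
            hit[hit] = cache.idx[p][pos[hit]] == obs[hit]
            resid = (y - state.alpha[s] - (total - old))[hit]
            f_new = _draw_f(cache, p, pos[hit], resid, state.sigma2, rng)
            state.f_values[p][:, s] = f_new
            total = total - old + contrib(p)
        else:
            state.f_values[p][:, s] = cache.prior_draw(p, rng)
    return state


# ---------------------------------------------------------------------------
# structure block (marginalized Metropolis-Hastings)
# ---------------------------------------------------------------------------


def _structure_log_target(Z, sigma2, gamma2, hp, precomp) -> float:
    lp = log_structure_prior(Z, sigma2, gamma2, hp)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_marginal_likelihood(Z, sigma2, gamma2, precomp=precomp)


def mh_update_structure(
    state: LatentState,
    X: AffinityMatrix,
    Y: SensitivityMatrix,
    hp: HyperParams,
    config: SamplerConfig,
    rng: np.random.Generator,
    precomp: MarginalPrecomp | None = None,
    counters: dict[str, list[int]] | None = None,
) -> LatentState:
    """One MH sweep on (Z, sigma^2, gamma^2) targeting the marginalized posterior.

    Single-flip proposals for each z_p in random order, then log-normal
    random-walk proposals for sigma^2 and gamma^2 (with Jacobian).
    """
    if precomp is None:
        precomp = MarginalPrecomp(X, Y, hp.kernel)
    state = state.copy()
    cur = _structure_log_target(state.Z, state.sigma2, state.gamma2, hp, precomp)

    for p in rng.permutation(X.n_proteins):
        Z_prop = state.Z.copy()
        Z_prop[p] = 1 - Z_prop[p]
        prop = _structure_log_target(Z_prop, state.sigma2, state.gamma2, hp, precomp)
        accept = np.log(rng.uniform()) < prop - cur
        if accept:
            state.Z = Z_prop
            cur = prop
        if counters is not None:
            counters["z"].append(int(accept))

    if config.update_sigma2:
        s2_prop = state.sigma2 * np.exp(config.proposal_scale_sigma2 * rng.standard_normal())
        prop = _structure_log_target(state.Z, s2_prop, state.gamma2, hp, precomp)
        log_ratio = prop - cur + np.log(s2_prop) - np.log(state.sigma2)
        accept = np.log(rng.uniform()) < log_ratio
        if accept:
            state.sigma2 = float(s2_prop)
            cur = prop
        if counters is not None:
            counters["sigma2"].append(int(accept))

    if config.update_gamma2:
        g2_prop = state.gamma2 * np.exp(config.proposal_scale_gamma2 * rng.standard_normal())
        prop = _structure_log_target(state.Z, state.sigma2, g2_prop, hp, precomp)
        log_ratio = prop - cur + np.log(g2_prop) - np.log(state.gamma2)
        accept = np.log(rng.uniform()) < log_ratio
        if accept:
            state.gamma2 = float(g2_prop)
        if counters is not None:
            counters["gamma2"].append(int(accept))
    return state


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _initial_state(X: AffinityMatrix, S: int, hp: HyperParams,
                   config: SamplerConfig, rng: np.random.Generator) -> LatentState:
    Z = (rng.uniform(size=X.n_proteins) < hp.pi0).astype(np.int8)
    f_values = [np.zeros((X.present_indices(p).size, S)) for p in range(X.n_proteins)]
    return LatentState(Z=Z, alpha=np.zeros(S), sigma2=config.sigma2_init,
                       gamma2=config.gamma2_init, f_values=f_values)


def run_mcmc(
    X: AffinityMatrix,
    Y: SensitivityMatrix,
    hp: HyperParams,
    config: SamplerConfig,
) -> PosteriorSamples:
    """Run the two-block sampler; returns post-burn-in states of all chains.

    Chains are initialized independently (z_p ~ Bernoulli(pi0), sigma^2 =
    gamma^2 = 1, alpha = 0, f = 0) from streams spawned off ``config.seed``,
    so results are exactly reproducible.
    """
    precomp = MarginalPrecomp(X, Y, hp.kernel)
    cache = BackfitCache(X, hp.kernel)
    S = Y.n_samples
    chains: list[list[LatentState]] = []
    log_posts: list[np.ndarray] = []
    counters = {"z": [], "sigma2": [], "gamma2": []}
    for child in np.random.SeedSequence(config.seed).spawn(config.n_chains):
        rng = np.random.default_rng(child)
        state = _initial_state(X, S, hp, config, rng)
        kept: list[LatentState] = []
        lps: list[float] = []
        for it in range(config.n_iter):
            try:
                state = mh_update_structure(state, X, Y, hp, config, rng,
                                            precomp=precomp, counters=counters)
                for s in range(S):
                    state = backfit_update(state, s, X, Y, hp, rng, cache=cache)
            except linalg.LinAlgError as exc:
                raise linalg.LinAlgError(
                    f"numerical failure at iteration {it}: {exc}"
                ) from exc
            if it >= config.burn_in:
                kept.append(state.copy())
                lps.append(_structure_log_target(state.Z, state.sigma2,
                                                 state.gamma2, hp, precomp))
        chains.append(kept)
        log_posts.append(np.asarray(lps))
    rates = {k: (float(np.mean(v)) if v else float("nan")) for k, v in counters.items()}
    return PosteriorSamples(chains=chains, log_posterior=log_posts,
                            acceptance_rates=rates, config=config, hp=hp,
                            protein_ids=list(X.protein_ids))


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def inclusion_probabilities(samples: PosteriorSamples) -> np.ndarray:
    """Posterior inclusion probability of each protein (pooled over chains)."""
    states = samples.states
    if not states:
        raise ValueError("no retained samples")
    return np.mean([st.Z for st in states], axis=0)


def select_proteins(samples: PosteriorSamples, threshold: float = 0.95) -> set[str]:
    """Proteins whose inclusion probability strictly exceeds ``threshold``.

    The default implements the 'z_p = 1 for more than 95% of the MCMC
    samples' selection rule.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    pip = inclusion_probabilities(samples)
    ids = samples.protein_ids or [str(p) for p in range(pip.size)]
    return {ids[p] for p in np.flatnonzero(pip > threshold)}


def posterior_predict(samples: PosteriorSamples, X: AffinityMatrix,
                      Y: SensitivityMatrix | None = None) -> np.ndarray:
    """Posterior-mean prediction Yhat: average of mu_ds over retained states.

    Defined for every (d, s) cell, observed or missing; missing affinity
    entries contribute zero to the mean.
    """
    states = samples.states
    if not states:
        raise ValueError("no retained samples")
    if states[0].f_values and states[0].f_values[0].shape[0] != X.present_indices(0).size:
        raise ValueError("samples inconsistent with affinity matrix")
    out = np.zeros((X.n_drugs, states[0].alpha.size))
    for st in states:
        out += mean_matrix(st, X)
    return out / len(states)


def posterior_mean_curves(
    samples: PosteriorSamples,
    X: AffinityMatrix,
    p: int,
    grid,
    kernel=constrained_kernel,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Posterior mean of f_ps on ``grid`` for every sample s; shape (len(grid), S).

    Each retained state contributes the GP conditional mean of f_ps given
    its stored values at the design points (the zero function when
    z_p = 0); all curves pass through 0 at affinity 0.
    """
    grid = np.asarray(grid, dtype=float)
    states = samples.states
    if not states:
        raise ValueError("no retained samples")
    params = samples.hp.kernel
    idx = X.present_indices(p)
    x = X.values[idx, p]
    nzmask = x != 0.0
    x_nz = x[nzmask]
    S = states[0].alpha.size
    out = np.zeros((grid.size, S))
    if x_nz.size:
        K = kernel(x_nz[:, None], x_nz[None, :], params)
        K = K + jitter * params.nu1 * np.eye(x_nz.size)
        Kstar = kernel(grid[:, None], x_nz[None, :], params)
        cho = linalg.cho_factor(K, lower=True)
        proj = Kstar @ linalg.cho_solve(cho, np.eye(x_nz.size))
        for st in states:
            if st.Z[p]:
                out += proj @ st.f_values[p][nzmask, :]
    return out / len(states)


def gelman_rubin(samples: PosteriorSamples, which: str) -> float:
    """Classical multi-chain potential scale reduction factor R-hat.

    ``which`` is ``"sigma2"`` or ``"gamma2"``.  Uses the plain (non-split)
    between/within variance formula on the retained draws.
    """
    series = trace(samples, which)
    return gelman_rubin_from_series(series)


def gelman_rubin_from_series(series: list[np.ndarray]) -> float:
    """PSRF from per-chain series: sqrt(((n-1)/n W + B/n) / W)."""
    m = len(series)
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    n = len(series[0])
    if n < 10:
        raise ValueError("need at least 10 retained states per chain")
    arr = np.asarray(series)
    chain_means = arr.mean(axis=1)
    W = float(np.mean(arr.var(axis=1, ddof=1)))
    B_over_n = float(np.var(chain_means, ddof=1))
    if W == 0.0:
        return 1.0
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def trace(samples: PosteriorSamples, quantity: str) -> list[np.ndarray]:
    """Per-chain ordered series of a scalar summary.

    ``quantity`` is one of ``"log_posterior"`` (unnormalized: marginalized
    likelihood plus structure-level priors), ``"sigma2"`` or ``"gamma2"``.
    """
    if not samples.chains or not samples.chains[0]:
        raise ValueError("no retained samples")
    if quantity == "log_posterior":
        return [lp.copy() for lp in samples.log_posterior]
    if quantity in ("sigma2", "gamma2"):
        return [np.asarray([getattr(st, quantity) for st in chain])
                for chain in samples.chains]
    raise ValueError(f"unknown quantity {quantity!r}")
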