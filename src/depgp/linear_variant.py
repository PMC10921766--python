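"""Linear spike-and-slab variant: per-protein contributions beta_ps * X_dp.

Same additive structure, missingness conventions and spike-and-slab
selection as the GP model, but each protein contributes a straight line
through the origin with slope beta_ps ~ N(0, tau^2).  Marginalizing the
intercepts and slopes gives a per-sample Gaussian likelihood with
covariance

    Sigma_s = gamma^2 J + sigma^2 I + tau^2 * sum_p z_p x_p x_p^T

restricted to the observed rows, where x_p is protein column p of X with
missing entries set to 0 — exactly the GP marginal under the linear kernel
k(x1, x2) = tau^2 x1 x2 (which already satisfies f(0) = 0).  The slope
prior scale tau^2 gets a Half-Normal(0, 1) hyperprior, mirroring the GP
amplitude, and is sampled in the structure block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core_model import (
    AffinityMatrix,
    HyperParams,
    SensitivityMatrix,
    _gaussian_logpdf_zero_mean,
    _log_halfnormal,
    log_structure_prior,
)
from .inference import PosteriorSamples, SamplerConfig, _draw_alpha
from .kernels import DEFAULT_JITTER

__all__ = [
    "LinearState",
    "linear_log_marginal_likelihood",
    "run_mcmc_linear",
    "mean_matrix_linear",
    "posterior_predict_linear",
]


@dataclass
class LinearState:
    """One MCMC state of the linear variant."""

    Z: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray  # (P, S) slopes
    sigma2: float
    gamma2: float
    tau2: float

    def copy(self) -> "LinearState":
        return LinearState(self.Z.copy(), self.alpha.copy(), self.beta.copy(),
                           self.sigma2, self.gamma2, self.tau2)


def _zero_filled(X: AffinityMatrix) -> np.ndarray:
    return np.where(X.present, X.values, 0.0)


def linear_log_marginal_likelihood(
    Z,
    sigma2: float,
    gamma2: float,
    tau2: float,
    X: AffinityMatrix,
    Y: SensitivityMatrix,
    jitter: float = DEFAULT_JITTER,
) -> float:
    """Observed-data log-likelihood with alpha and all slopes integrated out."""
    if sigma2 <= 0 or gamma2 <= 0 or tau2 <= 0:
        raise ValueError("variances must be positive")
    Z = np.asarray(Z)
    active = np.flatnonzero(Z)
    Xt = _zero_filled(X)
    eps = jitter * tau2
    total = 0.0
    for s in range(Y.n_samples):
        idx = Y.observed_indices(s)
        n = idx.size
        if n == 0:
            continue
        cov = np.full((n, n), gamma2) + (sigma2 + eps) * np.eye(n)
        if active.size:
            A = Xt[np.ix_(idx, active)]
            cov += tau2 * (A @ A.T)
        total += _gaussian_logpdf_zero_mean(Y.values[idx, s], cov)
    return float(total)


def mean_matrix_linear(state: LinearState, X: AffinityMatrix) -> np.ndarray:
    """D x S conditional-mean matrix alpha_s + sum_p z_p x_dp beta_ps."""
    Xt = _zero_filled(X)
    zb = state.beta * state.Z[:, None]
    return state.alpha[None, :] + Xt @ zb


def _linear_log_target(Z, sigma2, gamma2, tau2, X, Y, hp) -> float:
    lp = log_structure_prior(Z, sigma2, gamma2, hp) + _log_halfnormal(tau2)
    if not np.isfinite(lp):
        return -np.inf
    return lp + linear_log_marginal_likelihood(Z, sigma2, gamma2, tau2, X, Y)


def run_mcmc_linear(
    X: AffinityMatrix,
    Y: SensitivityMatrix,
    hp: HyperParams,
    config: SamplerConfig,
    proposal_scale_tau2: float = 0.2,
    update_tau2: bool = True,
    tau2_init: float = 1.0,
) -> PosteriorSamples:
    """Two-block sampler for the linear variant (see :func:`run_mcmc`).

    The structure block updates (Z, sigma^2, gamma^2, tau^2) against the
    marginalized likelihood; the conjugate block redraws alpha_s and the
    slopes beta_ps from their normal full conditionals.
    """
    Xt = _zero_filled(X)
    S = Y.n_samples
    P = X.n_proteins
    obs_idx = [Y.observed_indices(s) for s in range(S)]
    chains: list[list[LinearState]] = []
    log_posts: list[np.ndarray] = []
    counters = {"z": [], "sigma2": [], "gamma2": [], "tau2": []}
    for child in np.random.SeedSequence(config.seed).spawn(config.n_chains):
        rng = np.random.default_rng(child)
        state = LinearState(
            Z=(rng.uniform(size=P) < hp.pi0).astype(np.int8),
            alpha=np.zeros(S), beta=np.zeros((P, S)),
            sigma2=config.sigma2_init, gamma2=config.gamma2_init, tau2=tau2_init,
        )
        kept: list[LinearState] = []
        lps: list[float] = []
        for it in range(config.n_iter):
            state = state.copy()
            cur = _linear_log_target(state.Z, state.sigma2, state.gamma2,
                                     state.tau2, X, Y, hp)
            for p in rng.permutation(P):
                Zp = state.Z.copy()
                Zp[p] = 1 - Zp[p]
                prop = _linear_log_target(Zp, state.sigma2, state.gamma2,
                                          state.tau2, X, Y, hp)
                acc = np.log(rng.uniform()) < prop - cur
                if acc:
                    state.Z, cur = Zp, prop
                counters["z"].append(int(acc))
            for name, scale, on in (
                ("sigma2", config.proposal_scale_sigma2, config.update_sigma2),
                ("gamma2", config.proposal_scale_gamma2, config.update_gamma2),
                ("tau2", proposal_scale_tau2, update_tau2),
            ):
                if not on:
                    continue
                old = getattr(state, name)
                new = old * np.exp(scale * rng.standard_normal())
                kw = {"sigma2": state.sigma2, "gamma2": state.gamma2,
                      "tau2": state.tau2}
                kw[name] = new
                prop = _linear_log_target(state.Z, kw["sigma2"], kw["gamma2"],
                                          kw["tau2"], X, Y, hp)
                acc = np.log(rng.uniform()) < prop - cur + np.log(new) - np.log(old)
                if acc:
                    setattr(state, name, float(new))
                    cur = prop
                counters[name].append(int(acc))

            # conjugate block: intercepts and slopes
            for s in range(S):
                idx = obs_idx[s]
                y = Y.values[idx, s]
                A = Xt[idx, :]
                zb = state.beta[:, s] * state.Z
                fit = A @ zb
                state.alpha[s] = _draw_alpha(y - fit, state.sigma2, state.gamma2, rng)
                for p in range(P):
                    if state.Z[p]:
                        x = A[:, p]
                        resid = y - state.alpha[s] - (fit - x * zb[p])
                        prec = 1.0 / state.tau2 + (x @ x) / state.sigma2
                        mean = (x @ resid / state.sigma2) / prec
                        new_b = mean + rng.standard_normal() / np.sqrt(prec)
                        fit += x * (new_b - zb[p])
                        zb[p] = new_b
                        state.beta[p, s] = new_b
                    else:
                        state.beta[p, s] = np.sqrt(state.tau2) * rng.standard_normal()
            if it >= config.burn_in:
                kept.append(state.copy())
                lps.append(_linear_log_target(state.Z, state.sigma2, state.gamma2,
                                              state.tau2, X, Y, hp))
        chains.append(kept)
        log_posts.append(np.asarray(lps))
    rates = {k: (float(np.mean(v)) if v else float("nan")) for k, v in counters.items()}
    return PosteriorSamples(chains=chains, log_posterior=log_posts,
                            acceptance_rates=rates, config=config, hp=hp,
                            protein_ids=list(X.protein_ids))


def posterior_predict_linear(samples: PosteriorSamples, X: AffinityMatrix) -> np.ndarray:
    """Posterior-mean prediction under the linear variant."""
    states = samples.states
    if not states:
        raise ValueError("no retained samples")
    out = np.zeros((X.n_drugs, states[0].alpha.size))
    for st in states:
        out += mean_matrix_linear(st, X)
    return out / len(states)
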