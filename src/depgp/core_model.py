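"""Data containers, priors and the exact marginalized likelihood.

The model explains the D x S drug-sensitivity matrix Y additively: for
sample s and drug d,

    Y_ds = alpha_s + sum_p z_p 1(X_dp observed) f_ps(X_dp) + eps_ds,

where X is the D x P drug-protein affinity matrix, z_p ~ Bernoulli(pi0) is a
spike-and-slab inclusion indicator for protein p, f_ps ~ GP(0, k0) is the
protein's (nonlinear) contribution curve constrained to f_ps(0) = 0,
alpha_s | gamma^2 ~ N(0, gamma^2), gamma^2 ~ Half-Normal(0, 1),
eps_ds ~ N(0, sigma^2) and sigma^2 ~ Inv-Gamma(a0, b0).

Missing data need no imputation.  A missing affinity X_dp contributes
exactly zero to the mean of Y_ds; missing sensitivity entries are dropped
from the likelihood, which stays a product of per-sample Gaussians over the
observed entries.  Integrating out alpha_s and every f_ps analytically gives
the marginalized likelihood used by the structure-level sampler:

    Y_{-M_s} | X, Z, sigma^2, gamma^2 ~ N(0, Sigma_s),
    Sigma_s = gamma^2 J + sigma^2 I + sum_p z_p Kbar^(p)  (observed rows/cols)

with J the all-ones matrix and Kbar^(p) the missingness-masked constrained
kernel matrix of protein column p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import gammaln

from .kernels import (
    DEFAULT_JITTER,
    KernelParams,
    constrained_kernel,
    masked_kernel_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityMatrix",
    "SensitivityMatrix",
    "HyperParams",
    "LatentState",
    "MarginalPrecomp",
    "conditional_mean",
    "mean_matrix",
    "log_likelihood_conditional",
    "log_marginal_likelihood",
    "log_structure_prior",
    "log_prior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class AffinityMatrix:
    """D x P drug-protein affinity scores with an explicit missingness mask.

    ``values`` holds NaN where an entry is missing; ``present`` is the
    corresponding boolean mask (J_dp).  Protein columns with no present
    entry are unidentifiable (their kernel matrix is all zero) and are
    dropped by :meth:`from_dataframe` with a warning.
    """

    values: np.ndarray
    present: np.ndarray
    drug_ids: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.values.shape != self.present.shape:
            raise ValueError("values and present must have the same shape")
        D, P = self.values.shape
        if len(self.drug_ids) != D or len(self.protein_ids) != P:
            raise ValueError("label lengths inconsistent with matrix shape")
        if not np.all(np.isfinite(self.values[self.present])):
            raise ValueError("present affinity entries must be finite")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def present_indices(self, p: int) -> np.ndarray:
        """Drug indices with an observed affinity for protein column p."""
        return np.flatnonzero(self.present[:, p])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AffinityMatrix":
        """Build from a drugs-as-rows DataFrame, dropping all-missing columns."""
        values = df.to_numpy(dtype=float)
        present = ~np.isnan(values)
        keep = present.any(axis=0)
        if not keep.all():
            dropped = [str(c) for c, k in zip(df.columns, keep) if not k]
            logger.warning(
                "dropping %d protein column(s) with no observed affinity: %s",
                len(dropped), ", ".join(dropped),
            )
            values, present = values[:, keep], present[:, keep]
            cols = [str(c) for c, k in zip(df.columns, keep) if k]
        else:
            cols = [str(c) for c in df.columns]
        return cls(values, present, [str(i) for i in df.index], cols)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.protein_ids)


@dataclass
class SensitivityMatrix:
    """D x S drug-sensitivity responses with per-column missing index sets."""

    values: np.ndarray
    observed: np.ndarray
    drug_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed must have the same shape")
        D, S = self.values.shape
        if len(self.drug_ids) != D or len(self.sample_ids) != S:
            raise ValueError("label lengths inconsistent with matrix shape")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed sensitivity entries must be finite")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def observed_indices(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.observed[:, s])

    @property
    def missing_sets(self) -> list[np.ndarray]:
        """M_s: per-column indices of missing entries."""
        return [np.flatnonzero(~self.observed[:, s]) for s in range(self.n_samples)]

    def check_identifiable(self, min_observed: int = 2) -> None:
        """Raise if any sample column has fewer than ``min_observed`` entries."""
        counts = self.observed.sum(axis=0)
        bad = np.flatnonzero(counts < min_observed)
        if bad.size:
            names = ", ".join(self.sample_ids[s] for s in bad)
            raise ValueError(
                f"sample column(s) with fewer than {min_observed} observed entries: {names}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SensitivityMatrix":
        values = df.to_numpy(dtype=float)
        return cls(values, ~np.isnan(values),
                   [str(i) for i in df.index], [str(c) for c in df.columns])

    def to_dataframe(self) -> pd.DataFrame:
        vals = np.where(self.observed, self.values, np.nan)
        return pd.DataFrame(vals, index=self.drug_ids, columns=self.sample_ids)

    def with_values(self, values: np.ndarray, observed: np.ndarray) -> "SensitivityMatrix":
        return SensitivityMatrix(values, observed, list(self.drug_ids), list(self.sample_ids))


@dataclass(frozen=True)
class HyperParams:
    """Model hyperparameters.

    Defaults a0 = b0 = 1, pi0 = 0.1 are the recommended settings; the fit is
    insensitive to them and is driven primarily by the kernel parameters.
    """

    kernel: KernelParams
    a0: float = 1.0
    b0: float = 1.0
    pi0: float = 0.1

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("a0 and b0 must be positive")
        if not (0.0 < self.pi0 < 1.0):
            raise ValueError("pi0 must lie in (0, 1)")


@dataclass
class LatentState:
    """One MCMC state of the model.

    ``f_values[p]`` has shape (n_p, S): values of f_ps at the present design
    points of protein column p (row order = ``AffinityMatrix.present_indices(p)``)
    for every sample s.  Design points exactly 0 carry f = 0.
    """

    Z: np.ndarray
    alpha: np.ndarray
    sigma2: float
    gamma2: float
    f_values: list[np.ndarray] = field(default_factory=list)

    def copy(self) -> "LatentState":
        return LatentState(
            Z=self.Z.copy(),
            alpha=self.alpha.copy(),
            sigma2=self.sigma2,
            gamma2=self.gamma2,
            f_values=[f.copy() for f in self.f_values],
        )


# ---------------------------------------------------------------------------
# conditional (unmarginalized) quantities
# ---------------------------------------------------------------------------


def mean_matrix(state: LatentState, X: AffinityMatrix) -> np.ndarray:
    """D x S matrix of conditional means mu_ds given the latent state."""
    D, S = X.n_drugs, state.alpha.shape[0]
    mu = np.tile(state.alpha, (D, 1))
    for p in np.flatnonzero(state.Z):
        idx = X.present_indices(p)
        mu[idx, :] += state.f_values[p]
    return mu


def conditional_mean(state: LatentState, X: AffinityMatrix, d: int, s: int) -> float:
    """mu_ds = alpha_s + sum_p z_p 1(X_dp observed) f_ps(X_dp)."""
    if not (0 <= d < X.n_drugs) or not (0 <= s < state.alpha.shape[0]):
        raise IndexError("drug or sample index out of range")
    total = float(state.alpha[s])
    for p in np.flatnonzero(state.Z):
        if X.present[d, p]:
            pos = int(np.searchsorted(X.present_indices(p), d))
            total += float(state.f_values[p][pos, s])
    return total


def log_likelihood_conditional(
    state: LatentState, X: AffinityMatrix, Y: SensitivityMatrix
) -> float:
    """Gaussian log-likelihood of observed Y entries given all parameters."""
    if state.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    mu = mean_matrix(state, X)
    resid = Y.values[Y.observed] - mu[Y.observed]
    n = resid.size
    return float(-0.5 * n * (_LOG_2PI + np.log(state.sigma2))
                 - 0.5 * np.sum(resid**2) / state.sigma2)


# ---------------------------------------------------------------------------
# marginalized likelihood
# ---------------------------------------------------------------------------


class MarginalPrecomp:
    """Per-sample restricted kernel stacks reused across likelihood calls.

    For each sample s, stores the P masked constrained Gram matrices
    restricted to the observed rows of column s, stacked as (P, n_s, n_s).
    """

    def __init__(self, X: AffinityMatrix, Y: SensitivityMatrix,
                 params: KernelParams, kernel=constrained_kernel) -> None:
        self.params = params
        self.kernel = kernel
        self.obs_idx = [Y.observed_indices(s) for s in range(Y.n_samples)]
        self.y_obs = [Y.values[idx, s] for s, idx in enumerate(self.obs_idx)]
        full = [
            masked_kernel_matrix(X.values[:, p], X.present[:, p], params, kernel).values
            for p in range(X.n_proteins)
        ]
        self.kernel_stacks = [
            np.stack([K[np.ix_(idx, idx)] for K in full]) if idx.size else
            np.zeros((X.n_proteins, 0, 0))
            for idx in self.obs_idx
        ]


def _gaussian_logpdf_zero_mean(y: np.ndarray, cov: np.ndarray) -> float:
    """log N(y; 0, cov) via Cholesky; raises LinAlgError if not PD."""
    L = linalg.cholesky(cov, lower=True)
    alpha = linalg.solve_triangular(L, y, lower=True)
    return float(
        -0.5 * y.size * _LOG_2PI - np.sum(np.log(np.diag(L))) - 0.5 * alpha @ alpha
    )


def log_marginal_likelihood(
    Z,
    sigma2: float,
    gamma2: float,
    X: AffinityMatrix | None = None,
    Y: SensitivityMatrix | None = None,
    kernel_params: KernelParams | None = None,
    kernel=constrained_kernel,
    precomp: MarginalPrecomp | None = None,
    jitter: float = DEFAULT_JITTER,
) -> float:
    """Log-likelihood of the observed Y with alpha and all f_ps integrated out.

    Sums, over samples, log N(Y_{-M_s}; 0, Sigma_s) with
    Sigma_s = gamma^2 J + sigma^2 I + sum_p z_p Kbar^(p) restricted to the
    observed rows.  Either pass (X, Y, kernel_params) or a prebuilt
    :class:`MarginalPrecomp`.
    """
    if sigma2 <= 0 or gamma2 <= 0:
        raise ValueError("sigma2 and gamma2 must be positive")
    if precomp is None:
        if X is None or Y is None or kernel_params is None:
            raise TypeError("pass either precomp or (X, Y, kernel_params)")
        precomp = MarginalPrecomp(X, Y, kernel_params, kernel)
    Z = np.asarray(Z)
    active = np.flatnonzero(Z)
    eps = jitter * precomp.params.nu1
    total = 0.0
    for y, stack in zip(precomp.y_obs, precomp.kernel_stacks):
        n = y.size
        if n == 0:
            continue
        cov = np.full((n, n), gamma2) + (sigma2 + eps) * np.eye(n)
        if active.size:
            cov += stack[active].sum(axis=0)
        try:
            total += _gaussian_logpdf_zero_mean(y, cov)
        except linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
            raise linalg.LinAlgError(
                "marginal covariance not factorizable after jitter; "
                "inputs are numerically degenerate"
            ) from exc
    return total


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def _log_invgamma(x: float, a0: float, b0: float) -> float:
    if x <= 0:
        return -np.inf
    return a0 * np.log(b0) - gammaln(a0) - (a0 + 1.0) * np.log(x) - b0 / x


def _log_halfnormal(x: float) -> float:
    # Half-Normal(0, 1) on the variance parameter itself
    if x <= 0:
        return -np.inf
    return 0.5 * np.log(2.0 / np.pi) - 0.5 * x * x


def log_structure_prior(Z, sigma2: float, gamma2: float, hp: HyperParams) -> float:
    """Log prior of the marginalized block (Z, sigma^2, gamma^2)."""
    Z = np.asarray(Z)
    k = int(Z.sum())
    lp = k * np.log(hp.pi0) + (Z.size - k) * np.log1p(-hp.pi0)
    lp += _log_invgamma(sigma2, hp.a0, hp.b0)
    lp += _log_halfnormal(gamma2)
    return float(lp)


def log_prior(
    state: LatentState,
    hp: HyperParams,
    X: AffinityMatrix | None = None,
    jitter: float = DEFAULT_JITTER,
) -> float:
    """Joint log prior of a full latent state; -inf outside the support.

    The GP prior terms for the stored f_ps values require the affinity
    matrix ``X`` (for the design points); they are skipped when ``X`` is
    None or the state carries no function values.
    """
    lp = log_structure_prior(state.Z, state.sigma2, state.gamma2, hp)
    if not np.isfinite(lp):
        return float(lp)
    lp += float(np.sum(stats.norm.logpdf(state.alpha, 0.0, np.sqrt(state.gamma2))))
    if X is not None and state.f_values:
        for p in range(X.n_proteins):
            idx = X.present_indices(p)
            if idx.size == 0:
                continue
            x = X.values[idx, p]
            K = constrained_kernel(x[:, None], x[None, :], hp.kernel)
            K = K + jitter * hp.kernel.nu1 * np.eye(idx.size)
            f = state.f_values[p]
            L = linalg.cholesky(K, lower=True)
            for s in range(f.shape[1]):
                a = linalg.solve_triangular(L, f[:, s], lower=True)
                lp += float(
                    -0.5 * idx.size * _LOG_2PI
                    - np.sum(np.log(np.diag(L)))
                    - 0.5 * a @ a
                )
    return float(lp)
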