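"""Kernel functions for the constrained Gaussian process prior.

Each per-protein contribution function f_ps is given a zero-mean GP prior
whose sample paths vanish at affinity zero: a drug with affinity score 0
does not bind the protein and therefore cannot contribute to the response.
The constraint is imposed by conditioning an unconstrained GP on f(0) = 0,
which yields the modified kernel

    k0(x1, x2) = k(x1, x2) - k(x1, 0) k(x2, 0) / k(0, 0).

With the Gaussian-RBF base kernel k(x1, x2) = nu1 exp(-(x1-x2)^2 / (2 nu2^2))
this simplifies to nu1 [exp(-(x1-x2)^2/(2 nu2^2)) - exp(-(x1^2+x2^2)/(2 nu2^2))].

Kernel matrices over a protein's affinity column additionally zero out every
row/column whose design point is missing, so that missing affinity entries
contribute exactly nothing to the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "MaskedKernelMatrix",
    "rbf_kernel",
    "constrained_kernel",
    "linear_kernel",
    "gram_matrix",
    "sample_gp_paths",
    "masked_kernel_matrix",
    "DEFAULT_JITTER",
]

#: Relative diagonal jitter (scaled by the kernel amplitude) added to any
#: Gram matrix that has to be factorized; duplicate design points otherwise
#: make the matrix exactly singular.
DEFAULT_JITTER = 1e-6


@dataclass(frozen=True)
class KernelParams:
    """Amplitude and length-scale of the 1D Gaussian-RBF kernel.

    Parameters
    ----------
    nu1
        Kernel amplitude (prior variance of the unconstrained GP), > 0.
    nu2
        Length-scale on the affinity axis, > 0.
    """

    nu1: float
    nu2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.nu1) and self.nu1 > 0):
            raise ValueError(f"nu1 must be a positive finite real, got {self.nu1!r}")
        if not (np.isfinite(self.nu2) and self.nu2 > 0):
            raise ValueError(f"nu2 must be a positive finite real, got {self.nu2!r}")


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("kernel inputs must be finite")


def rbf_kernel(x1, x2, params: KernelParams):
    """1D Gaussian-RBF kernel nu1 * exp(-(x1-x2)^2 / (2 nu2^2)).

    Accepts scalars or broadcastable arrays; returns the same shape.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    _check_finite(x1, x2)
    out = params.nu1 * np.exp(-((x1 - x2) ** 2) / (2.0 * params.nu2**2))
    return out if out.ndim else float(out)


def constrained_kernel(x1, x2, params: KernelParams):
    """Kernel of the GP conditioned on f(0) = 0.

    k0(x1,x2) = k(x1,x2) - k(x1,0) k(x2,0) / k(0,0); every sample path of a
    zero-mean GP with this kernel passes through the origin.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    _check_finite(x1, x2)
    out = params.nu1 * (
        np.exp(-((x1 - x2) ** 2) / (2.0 * params.nu2**2))
        - np.exp(-(x1**2 + x2**2) / (2.0 * params.nu2**2))
    )
    return out if out.ndim else float(out)


def linear_kernel(x1, x2, params: KernelParams):
    """Homogeneous linear kernel nu1 * x1 * x2 (satisfies f(0)=0 already).

    ``params.nu1`` plays the role of the slope prior variance; ``nu2`` is
    ignored.  Used by the linear model variant.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    _check_finite(x1, x2)
    out = params.nu1 * x1 * x2
    return out if out.ndim else float(out)


def gram_matrix(x, params: KernelParams, kernel=constrained_kernel, jitter: float | None = None) -> np.ndarray:
    """Gram matrix of ``kernel`` on the points ``x`` (1D array).

    ``jitter`` (relative to nu1) is added to the diagonal when given;
    pass :data:`DEFAULT_JITTER` before factorizing.
    """
    x = np.asarray(x, dtype=float)
    K = kernel(x[:, None], x[None, :], params)
    if jitter is not None:
        K = K + jitter * params.nu1 * np.eye(len(x))
    return K


def sample_gp_paths(
    x,
    params: KernelParams,
    n_paths: int,
    rng: np.random.Generator,
    kernel=constrained_kernel,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Draw zero-mean GP sample paths at the points ``x``; shape (len(x), n_paths).

    Points with zero prior variance (for the constrained kernel, x = 0) are
    degenerate — the process equals 0 there surely — so they are pinned to 0
    exactly and excluded from the factorized block; the diagonal jitter is
    applied only to the non-degenerate submatrix.
    """
    from scipy import linalg

    x = np.asarray(x, dtype=float)
    var = kernel(x, x, params)
    live = np.flatnonzero(np.atleast_1d(var) > 0.0)
    out = np.zeros((x.size, n_paths))
    if live.size:
        xl = x[live]
        K = kernel(xl[:, None], xl[None, :], params) + jitter * params.nu1 * np.eye(live.size)
        L = linalg.cholesky(K, lower=True)
        out[live] = L @ rng.standard_normal((live.size, n_paths))
    return out


@dataclass(frozen=True)
class MaskedKernelMatrix:
    """D x D kernel matrix of one protein column with missing rows zeroed.

    ``values[d1, d2]`` is the constrained kernel of the two affinity scores
    when both are present and exactly 0 otherwise.
    """

    values: np.ndarray
    design_points: np.ndarray  # affinity scores, NaN where missing
    present: np.ndarray  # boolean mask

    def restricted(self, idx: np.ndarray) -> np.ndarray:
        """Principal submatrix on the row indices ``idx``."""
        return self.values[np.ix_(idx, idx)]


def masked_kernel_matrix(
    column_values,
    present=None,
    params: KernelParams | None = None,
    kernel=constrained_kernel,
) -> MaskedKernelMatrix:
    """Kernel matrix of one affinity column, zeroed where either point is missing.

    Parameters
    ----------
    column_values
        Length-D array of affinity scores; NaN marks missing entries unless
        ``present`` is given explicitly.
    present
        Optional boolean mask; defaults to ``~isnan(column_values)``.
    params
        Kernel parameters (required).
    kernel
        Kernel function, by default the constrained RBF.
    """
    x = np.asarray(column_values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("column_values must be a non-empty 1D array")
    if params is None:
        raise TypeError("params is required")
    if present is None:
        present = ~np.isnan(x)
    present = np.asarray(present, dtype=bool)
    D = x.size
    K = np.zeros((D, D))
    idx = np.flatnonzero(present)
    if idx.size:
        xi = x[idx]
        if not np.all(np.isfinite(xi)):
            raise ValueError("present affinity values must be finite")
        K[np.ix_(idx, idx)] = kernel(xi[:, None], xi[None, :], params)
    return MaskedKernelMatrix(values=K, design_points=np.where(present, x, np.nan), present=present)
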