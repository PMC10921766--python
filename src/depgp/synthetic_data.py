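"""Synthetic datasets drawn from the generative model.

Emulates the structure of drug screen data — D drugs profiled against P
proteins with heavy missingness in the affinity matrix, S samples with
moderate missingness in the response matrix, and only a few informative
proteins — at a scale where ground truth is identifiable.  Contribution
curves can be drawn from the constrained-kernel GP itself (``gp_draw``),
set to non-monotonic cap shapes c * x * (1 - x) like the nonlinear
dependency patterns the GP model is designed to capture (``cap_shape``),
or made linear through the origin (``linear``).

Affinity scores live on (0, 1), matching the scale the default kernel
length-scale grid is calibrated to.  The default missingness rate for X is
0.6 rather than the ~0.9 typical of real kinobead screens, so that small
test instances keep at least a few design points per protein; the
``paper_like`` preset uses 0.9 at D >= 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .core_model import AffinityMatrix, LatentState, SensitivityMatrix
from .kernels import DEFAULT_JITTER, KernelParams, constrained_kernel

__all__ = ["ScenarioConfig", "GroundTruth", "SyntheticDataset", "generate",
           "mask_additional", "preset"]

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings; the defaults define the standard test scenario."""

    D: int = 30
    P: int = 8
    S: int = 5
    n_active: int = 2
    kernel: KernelParams = field(default_factory=lambda: KernelParams(0.155, 0.126))
    sigma2_true: float = 0.05
    gamma2_true: float = 0.25
    x_missing_rate: float = 0.6
    y_missing_rate: float = 0.1
    shape: str = "gp_draw"
    seed: int = 0
    min_points_per_protein: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.n_active <= self.P):
            raise ValueError("need 0 < n_active <= P")
        if not (0.0 <= self.x_missing_rate < 1.0 and 0.0 <= self.y_missing_rate < 1.0):
            raise ValueError("missingness rates must lie in [0, 1)")
        if self.sigma2_true < 0 or self.gamma2_true <= 0:
            raise ValueError("variance parameters must be positive")
        if self.shape not in ("gp_draw", "cap_shape", "linear"):
            raise ValueError(f"unknown shape {self.shape!r}")


_PRESETS = {
    "default": {},
    "paper_like": {"D": 120, "P": 20, "S": 8, "n_active": 3, "x_missing_rate": 0.9},
    "linear": {"shape": "linear"},
    "cap": {"shape": "cap_shape"},
}


def preset(name: str, **overrides) -> ScenarioConfig:
    """Named scenario presets: default, paper_like, linear, cap."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return replace(ScenarioConfig(**_PRESETS[name]), **overrides)


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset."""

    Z: np.ndarray
    alpha: np.ndarray
    f_values: list[np.ndarray]  # (n_p, S) at the present points of column p
    sigma2: float
    gamma2: float
    shape: str

    def as_state(self) -> LatentState:
        sigma2 = self.sigma2 if self.sigma2 > 0 else 1e-12
        return LatentState(Z=self.Z.copy(), alpha=self.alpha.copy(),
                           sigma2=sigma2, gamma2=self.gamma2,
                           f_values=[f.copy() for f in self.f_values])


@dataclass
class SyntheticDataset:
    X: AffinityMatrix
    Y: SensitivityMatrix
    truth: GroundTruth

    def mean_matrix(self) -> np.ndarray:
        """Noise-free D x S mean surface of the generating model."""
        from .core_model import mean_matrix

        return mean_matrix(self.truth.as_state(), self.X)


def _draw_affinity(cfg: ScenarioConfig, rng: np.random.Generator):
    for _ in range(_MAX_RESAMPLE):
        values = rng.uniform(size=(cfg.D, cfg.P))
        present = rng.uniform(size=(cfg.D, cfg.P)) >= cfg.x_missing_rate
        if (present.sum(axis=0) >= cfg.min_points_per_protein).all():
            return np.where(present, values, np.nan), present
    raise RuntimeError(
        "could not draw an affinity mask keeping every protein column "
        f"at >= {cfg.min_points_per_protein} present entries"
    )


def _draw_curves(cfg: ScenarioConfig, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Values of f_ps at design points x for all S samples: shape (len(x), S)."""
    n = x.size
    if cfg.shape == "gp_draw":
        K = constrained_kernel(x[:, None], x[None, :], cfg.kernel)
        K = K + DEFAULT_JITTER * cfg.kernel.nu1 * np.eye(n)
        L = linalg.cholesky(K, lower=True)
        return L @ rng.standard_normal((n, cfg.S))
    # deterministic shape families with per-sample random coefficients
    sign = rng.choice([-1.0, 1.0], size=cfg.S)
    if cfg.shape == "cap_shape":
        c = sign * rng.uniform(2.0, 4.0, size=cfg.S)
        return (x * (1.0 - x))[:, None] * c[None, :]
    c = sign * rng.uniform(0.5, 1.5, size=cfg.S)
    return x[:, None] * c[None, :]


def generate(cfg: ScenarioConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model; reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    values, present = _draw_affinity(cfg, rng)
    drug_ids = [f"drug_{d:03d}" for d in range(cfg.D)]
    protein_ids = [f"protein_{p:02d}" for p in range(cfg.P)]
    sample_ids = [f"sample_{s:02d}" for s in range(cfg.S)]
    X = AffinityMatrix(values, present, drug_ids, protein_ids)

    active = np.sort(rng.choice(cfg.P, size=cfg.n_active, replace=False))
    Z = np.zeros(cfg.P, dtype=np.int8)
    Z[active] = 1
    alpha = np.sqrt(cfg.gamma2_true) * rng.standard_normal(cfg.S)
    f_values = []
    for p in range(cfg.P):
        idx = X.present_indices(p)
        if Z[p]:
            f_values.append(_draw_curves(cfg, X.values[idx, p], rng))
        else:
            f_values.append(np.zeros((idx.size, cfg.S)))
    truth = GroundTruth(Z=Z, alpha=alpha, f_values=f_values,
                        sigma2=cfg.sigma2_true, gamma2=cfg.gamma2_true,
                        shape=cfg.shape)

    mu = np.tile(alpha, (cfg.D, 1))
    for p in active:
        mu[X.present_indices(p), :] += f_values[p]
    y = mu + np.sqrt(cfg.sigma2_true) * rng.standard_normal((cfg.D, cfg.S))
    observed = rng.uniform(size=(cfg.D, cfg.S)) >= cfg.y_missing_rate
    # keep every sample column identifiable
    for s in range(cfg.S):
        short = 2 - int(observed[:, s].sum())
        if short > 0:
            hidden = np.flatnonzero(~observed[:, s])
            observed[rng.choice(hidden, size=short, replace=False), s] = True
    Y = SensitivityMatrix(np.where(observed, y, np.nan), observed, drug_ids, sample_ids)
    return SyntheticDataset(X=X, Y=Y, truth=truth)


def mask_additional(Y: SensitivityMatrix, rate: float, seed: int) -> SensitivityMatrix:
    """Mask additional observed cells at ``rate``, keeping >= 2 per column."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    observed = Y.observed.copy()
    cells = np.argwhere(observed)
    hit = cells[rng.uniform(size=cells.shape[0]) < rate]
    order = rng.permutation(hit.shape[0])
    counts = observed.sum(axis=0)
    for d, s in hit[order]:
        if counts[s] > 2:
            observed[d, s] = False
            counts[s] -= 1
    return Y.with_values(np.where(observed, Y.values, np.nan), observed)
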