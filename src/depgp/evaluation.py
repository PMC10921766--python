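"""Model evaluation: nMSE, IoU, and cross-validated kernel grid search.

Prediction error is the normalized mean square error

    nMSE(Y, Yhat) = ||Y - Yhat||^2 / ||Y - Ybar||^2

over observed cells, with Ybar the grand mean of the observed entries;
normalization makes the error comparable across response transformations.
Kernel hyperparameters nu = (nu1, nu2) are chosen by grid search with
3-fold cross-validation: the observed (d, s) cells are partitioned at
random, held-out cells are simply marked missing (the model handles them
natively — no imputation), and the held-out cells are scored from the
posterior-mean prediction.  Selected-protein sets are compared with the
intersection-over-union score IoU(A, B) = |A n B| / |A u B|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.model_selection import KFold

from .core_model import AffinityMatrix, HyperParams, SensitivityMatrix
from .inference import SamplerConfig, posterior_predict, run_mcmc, select_proteins
from .kernels import KernelParams
from .linear_variant import posterior_predict_linear, run_mcmc_linear

__all__ = ["CVConfig", "CVResult", "nmse", "iou", "cross_validate", "compare_selection"]

#: 5 x 6 default grid of kernel amplitudes and length-scales (30 points).
DEFAULT_NU1_GRID = (0.01, 0.0825, 0.155, 0.2275, 0.3000)
DEFAULT_NU2_GRID = (0.01, 0.068, 0.126, 0.184, 0.242, 0.3)


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 3
    nu1_grid: tuple = DEFAULT_NU1_GRID
    nu2_grid: tuple = DEFAULT_NU2_GRID
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.nu1_grid or not self.nu2_grid:
            raise ValueError("grids must be non-empty")


@dataclass
class CVResult:
    """Per-grid-point CV error and selections; ``best`` minimizes mean nMSE.

    Ties break toward the smallest nu1, then the smallest nu2 (favoring
    smoother models), which the sorted grid iteration order guarantees.
    """

    grid: list[KernelParams]
    mean_nmse: np.ndarray
    fold_nmse: np.ndarray  # (n_grid, n_folds)
    selections: list[set[str]] | None
    fold_seed: int
    best_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.best_index = int(np.argmin(self.mean_nmse))

    @property
    def best(self) -> KernelParams:
        return self.grid[self.best_index]


def nmse(y_true, y_hat) -> float:
    """||Y - Yhat||^2 / ||Y - Ybar||^2 over the finite cells of ``y_true``."""
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_true.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    mask = np.isfinite(y_true)
    y, yh = y_true[mask], y_hat[mask]
    if y.size < 2:
        raise ValueError("need at least 2 observed cells")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("zero variance in observed cells")
    return float(np.sum((y - yh) ** 2) / denom)


def iou(A, B) -> float:
    """Intersection over union of two label sets; IoU(empty, empty) = 1."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        return 1.0
    return len(A & B) / len(union)


def _fit_predict(X, Y_train, hp, sampler, model):
    if model == "gp":
        samples = run_mcmc(X, Y_train, hp, sampler)
        return samples, posterior_predict(samples, X)
    if model == "linear":
        samples = run_mcmc_linear(X, Y_train, hp, sampler)
        return samples, posterior_predict_linear(samples, X)
    raise ValueError(f"unknown model {model!r}")


def cross_validate(
    X: AffinityMatrix,
    Y: SensitivityMatrix,
    hp_base: HyperParams,
    cv: CVConfig,
    sampler: SamplerConfig,
    model: str = "gp",
    select: bool = True,
    selection_threshold: float = 0.95,
) -> CVResult:
    """Grid search over nu with k-fold CV on randomly partitioned cells.

    Held-out cells are marked missing in the training response matrix and
    predicted from the posterior mean; the per-fold nMSE is computed on the
    held-out cells only.  When ``select`` is true an additional full-data
    fit per grid point records the selected-protein set.
    """
    cells = np.argwhere(Y.observed)
    if cells.shape[0] < cv.n_folds:
        raise ValueError("fewer observed cells than folds")
    kf = KFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.fold_seed)
    folds = list(kf.split(cells))
    # build per-fold training matrices once, validating column coverage
    trains = []
    for train_rows, test_rows in folds:
        obs = np.zeros_like(Y.observed)
        dd, ss = cells[train_rows, 0], cells[train_rows, 1]
        obs[dd, ss] = True
        counts = obs.sum(axis=0)
        if (counts < 1).any():
            s = int(np.argmin(counts))
            raise ValueError(
                f"fold leaves sample column {Y.sample_ids[s]!r} with no observed cell"
            )
        trains.append(Y.with_values(np.where(obs, Y.values, np.nan), obs))

    grid = [KernelParams(n1, n2)
            for n1, n2 in product(sorted(cv.nu1_grid), sorted(cv.nu2_grid))]
    fold_scores = np.empty((len(grid), cv.n_folds))
    selections: list[set[str]] | None = [] if select else None
    for g, kp in enumerate(grid):
        hp = HyperParams(kernel=kp, a0=hp_base.a0, b0=hp_base.b0, pi0=hp_base.pi0)
        for f, (train_rows, test_rows) in enumerate(folds):
            _, yhat = _fit_predict(X, trains[f], hp, sampler, model)
            dd, ss = cells[test_rows, 0], cells[test_rows, 1]
            fold_scores[g, f] = nmse(Y.values[dd, ss], yhat[dd, ss])
        if select:
            samples, _ = _fit_predict(X, Y, hp, sampler, model)
            selections.append(select_proteins(samples, selection_threshold))
    return CVResult(grid=grid, mean_nmse=fold_scores.mean(axis=1),
                    fold_nmse=fold_scores, selections=selections,
                    fold_seed=cv.fold_seed)


def compare_selection(result: CVResult, reference) -> np.ndarray:
    """IoU of each grid point's selected-protein set against a reference set."""
    if result.selections is None:
        raise ValueError("CV result carries no selections (run with select=True)")
    ref = set(reference)
    return np.asarray([iou(sel, ref) for sel in result.selections])
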