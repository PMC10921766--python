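"""Reading/writing affinity and sensitivity tables, and response transforms.

Tables are delimited text (comma or tab, autodetected) with a header row of
column labels and a first column of row labels; drugs are rows.  NA tokens
become explicit missing flags — the model consumes missingness directly and
no imputation is performed anywhere.  Raw viability-type responses in (0,1)
are mapped to the real line with the data-independent logit transform;
positive-scale responses with the natural log.  A z-score path is kept for
compatibility with workflows that normalize Y per sample column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import AffinityMatrix, SensitivityMatrix

__all__ = [
    "RawTable",
    "read_matrix",
    "write_matrix",
    "to_affinity",
    "to_sensitivity",
    "logit_transform",
    "inverse_logit",
    "log_transform",
    "zscore_normalize",
]

DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan")


@dataclass
class RawTable:
    """Labelled rectangular table with explicit missing cells (drugs as rows)."""

    values: np.ndarray  # NaN where missing
    row_ids: list[str]
    col_ids: list[str]

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def read_matrix(path, na_tokens=DEFAULT_NA_TOKENS, transpose: bool = False) -> RawTable:
    """Parse a delimited text matrix with row/column labels.

    The delimiter (comma vs tab) is autodetected from the header line.
    Duplicate labels and non-numeric non-NA cells are errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(na_tokens),
                     keep_default_na=False, float_precision="round_trip")
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row labels: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column labels: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    return RawTable(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_matrix(table, path, sep: str = ",") -> None:
    """Write a RawTable / AffinityMatrix / SensitivityMatrix as delimited text.

    Missing cells are written as empty strings; values keep 17 significant
    digits so a read round-trip is lossless.
    """
    df = table.to_dataframe()
    df.to_csv(path, sep=sep, na_rep="", float_format="%.17g")


def to_affinity(table: RawTable) -> AffinityMatrix:
    """Interpret a raw table as the drug x protein affinity matrix X."""
    return AffinityMatrix.from_dataframe(table.to_dataframe())


def to_sensitivity(table: RawTable, min_observed: int = 2) -> SensitivityMatrix:
    """Interpret a raw table as the drug x sample sensitivity matrix Y."""
    Y = SensitivityMatrix.from_dataframe(table.to_dataframe())
    Y.check_identifiable(min_observed)
    return Y


def _transform(Y: SensitivityMatrix, fn, domain, domain_desc: str) -> SensitivityMatrix:
    vals = Y.values.copy()
    obs = Y.observed
    bad = obs & ~domain(vals)
    if bad.any():
        d, s = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"observed entry Y[{Y.drug_ids[d]!r}, {Y.sample_ids[s]!r}] = "
            f"{vals[d, s]!r} outside {domain_desc}"
        )
    vals[obs] = fn(vals[obs])
    vals[~obs] = np.nan
    return Y.with_values(vals, obs.copy())


def logit_transform(Y: SensitivityMatrix, clip_eps: float | None = None) -> SensitivityMatrix:
    """Map observed responses in (0, 1) to the real line via log(y / (1-y)).

    Boundary values are hard errors: silently clipping would hide a
    violated model assumption.  Pass ``clip_eps`` to opt in to clipping
    observed entries into [eps, 1-eps] first.
    """
    if clip_eps is not None:
        if not (0.0 < clip_eps < 0.5):
            raise ValueError("clip_eps must lie in (0, 0.5)")
        vals = Y.values.copy()
        vals[Y.observed] = np.clip(vals[Y.observed], clip_eps, 1.0 - clip_eps)
        Y = Y.with_values(vals, Y.observed.copy())
    with np.errstate(divide="ignore"):
        return _transform(Y, lambda v: np.log(v / (1.0 - v)),
                          lambda v: (v > 0.0) & (v < 1.0), "the open interval (0, 1)")


def inverse_logit(Y: SensitivityMatrix) -> SensitivityMatrix:
    """Inverse of :func:`logit_transform` on the observed cells."""
    from scipy.special import expit

    return _transform(Y, expit, lambda v: np.isfinite(v), "the reals")


def log_transform(Y: SensitivityMatrix) -> SensitivityMatrix:
    """Natural log of observed positive responses."""
    with np.errstate(divide="ignore"):
        return _transform(Y, np.log, lambda v: v > 0.0, "the positive reals")


def zscore_normalize(Y: SensitivityMatrix) -> SensitivityMatrix:
    """Per-column standardization over observed entries (sample s.d., n-1).

    Kept for compatibility with z-score-normalized workflows; note this is
    data-dependent, unlike logit/log.
    """
    vals = Y.values.copy()
    for s in range(Y.n_samples):
        idx = Y.observed_indices(s)
        if idx.size < 2:
            raise ValueError(f"column {Y.sample_ids[s]!r} has fewer than 2 observed entries")
        col = vals[idx, s]
        sd = np.std(col, ddof=1)
        if sd == 0.0:
            raise ValueError(f"column {Y.sample_ids[s]!r} has zero variance")
        vals[idx, s] = (col - col.mean()) / sd
    vals[~Y.observed] = np.nan
    return Y.with_values(vals, Y.observed.copy())
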