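"""Counts -> filtered, batch-adjusted log2-CPM expression matrices.

The expression scale for all downstream scoring is log2 counts-per-million
with a small prior count.  Batch adjustment residualizes an additive
fixed-effects fit (expression ~ group + batch + run_type per gene) and
subtracts only the nuisance (batch / run-type) contributions, so group
differences are protected.  No TMM/quantile normalization and no outlier
detection are performed here.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def cpm(counts: pd.DataFrame, prior_count: float = 0.0) -> pd.DataFrame:
    """Counts per million: ``(c + prior) / (L + 2*prior) * 1e6``.

    ``L`` is the per-sample library size (column sum of raw counts). The
    ``2*prior`` offset in the denominator keeps the companion log
    transform finite at zero counts.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0).astype(float)
    if prior_count == 0.0 and (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size with zero prior count: samples {bad}")
    return (counts + prior_count).div(lib + 2.0 * prior_count, axis=1) * 1e6


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count (default 0.5)."""
    return np.log2(cpm(counts, prior_count=prior_count))


def filter_low_expression(
    mat: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int = 3,
    scale: str = "counts",
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    ``scale="counts"`` computes CPM from the matrix itself (prior 0);
    ``scale="logcpm"`` treats values as log2-CPM and compares against
    ``log2(min_cpm)``.  Gene order is preserved; the operation is
    idempotent.  An empty result warns rather than errors.
    """
    if min_samples > mat.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {mat.shape[1]} available samples"
        )
    if scale == "counts":
        vals = cpm(mat, prior_count=0.0)
    elif scale == "logcpm":
        if min_cpm <= 0:
            raise ValueError("min_cpm must be positive on the log-CPM scale")
        vals = mat >= np.log2(min_cpm)
        keep = vals.sum(axis=1) >= min_samples
        out = mat.loc[keep]
        if out.shape[0] == 0:
            warnings.warn("filter_low_expression removed every gene", stacklevel=2)
        return out
    else:
        raise ValueError(f"unknown scale {scale!r}")
    keep = (vals >= min_cpm).sum(axis=1) >= min_samples
    out = mat.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("filter_low_expression removed every gene", stacklevel=2)
    return out


def _dummies(series: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummy columns (first level dropped, levels in order
    of appearance).  A single-level factor yields zero columns."""
    levels = list(dict.fromkeys(series))
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((series == lev).to_numpy(dtype=float))
        names.append(str(lev))
    if not cols:
        return np.empty((len(series), 0)), []
    return np.column_stack(cols), names


def batch_adjust(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    batch_cols: Sequence[str] = ("batch", "run_type"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Remove additive batch/run-type effects while protecting group effects.

    Per gene, fits ``expression ~ group + batch + run_type`` by least
    squares and subtracts the fitted nuisance contributions.  Nuisance
    columns that are linear combinations of other nuisance columns (e.g.
    run type fully determined by batch) are dropped silently; a nuisance
    column aliased with the group design raises, naming the factor.
    Idempotent to numerical tolerance.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    meta = meta.loc[list(expr.columns)]

    n = expr.shape[1]
    X_protect = [np.ones((n, 1))]
    gcols, _ = _dummies(meta[group_col])
    if gcols.shape[1]:
        X_protect.append(gcols)
    Xp = np.column_stack(X_protect)
    rank_p = np.linalg.matrix_rank(Xp)

    nuis_cols: list[np.ndarray] = []
    X_cur = Xp
    rank_cur = rank_p
    for col in batch_cols:
        if col not in meta.columns:
            raise ValueError(f"metadata lacks column {col!r}")
        dm, levels = _dummies(meta[col])
        for j, lev in enumerate(levels):
            cand = dm[:, j : j + 1]
            if np.linalg.matrix_rank(np.column_stack([Xp, cand])) == rank_p:
                raise ValueError(
                    f"batch factor {col!r} (level {lev!r}) is confounded with "
                    f"{group_col!r}; its effect cannot be separated"
                )
            trial = np.column_stack([X_cur, cand])
            r = np.linalg.matrix_rank(trial)
            if r > rank_cur:
                nuis_cols.append(cand)
                X_cur, rank_cur = trial, r
            else:
                logger.info(
                    "batch_adjust: dropping redundant nuisance column %s=%s", col, lev
                )

    if not nuis_cols:
        return expr.copy()

    X = X_cur  # [protect | nuisance]
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_protect = Xp.shape[1]
    nuis_fit = X[:, n_protect:] @ beta[n_protect:]
    out = pd.DataFrame(
        (Y - nuis_fit).T, index=expr.index, columns=expr.columns
    )
    return out
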