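"""Single-sample marker-set enrichment scoring.

The score follows the published GSVA construction for continuous
(log-CPM) expression:

1. **Kernel CDF.** For each gene g with values ``x_g1..x_gn`` across all
   samples jointly, a Gaussian-kernel estimate of the cumulative density
   is evaluated at each sample::

       z(g, s) = (1/n) * sum_k Phi((x_gs - x_gk) / h_g),   h_g = sd(x_g)/4

   Genes with zero spread get the uninformative midpoint z = 0.5.

2. **Symmetric ranks.** Within each sample, genes are ranked by z
   descending (rank 1 = largest; ties broken lexicographically by gene
   id) and mapped to the symmetric rank statistic
   ``r(g, s) = |p/2 - rank(g, s)|``, which is large at both extremes.

3. **Weighted random walk.** Walking genes in rank order, in-set steps
   add ``r^tau`` normalized by the in-set total, out-of-set steps subtract
   ``1/(p - |S|)``.  The enrichment score is
   ``max(0, max deviation) + min(0, min deviation)`` (``max_diff`` mode)
   or the signed maximum-magnitude deviation (``max_abs`` mode).  Scores
   lie in [-1, 1]; positive means the set sits toward the top of the
   sample's ranking (upregulated), negative toward the bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .catalog import DEFAULT_DELIM, MarkerCatalog

logger = logging.getLogger(__name__)


@dataclass
class WalkConfig:
    """Scoring parameters.

    tau : weight exponent on the symmetric rank statistic (default 1).
    score_mode : "max_diff" (sum of positive max and negative min
        deviations) or "max_abs" (signed largest-magnitude deviation).
    kernel : "gaussian" (kernel CDF, bandwidth sd/4) or "none"
        (empirical CDF).
    """

    tau: float = 1.0
    score_mode: str = "max_diff"
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.score_mode not in ("max_diff", "max_abs"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if self.kernel not in ("gaussian", "none"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def kernel_cdf(expr: pd.DataFrame, kernel: str = "gaussian", chunk: int = 256) -> pd.DataFrame:
    """Per-gene kernel-estimated CDF of expression, evaluated at each sample.

    Estimated jointly across all samples.  Requires >= 2 samples.
    Constant genes (sd = 0) are assigned z = 0.5 everywhere.
    """
    if expr.shape[1] < 2:
        raise ValueError("kernel_cdf needs at least 2 samples")
    X = expr.to_numpy(dtype=float)
    p, n = X.shape
    Z = np.empty_like(X)
    if kernel == "none":
        # empirical CDF: fraction of samples with value <= x_gs
        for start in range(0, p, chunk):
            sl = slice(start, min(start + chunk, p))
            blk = X[sl]
            Z[sl] = (blk[:, :, None] >= blk[:, None, :]).mean(axis=2)
        return pd.DataFrame(Z, index=expr.index, columns=expr.columns)
    sd = X.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        logger.info("kernel_cdf: %d constant gene(s) set to z = 0.5", int(const.sum()))
    h = np.where(const, 1.0, sd / 4.0)
    for start in range(0, p, chunk):
        sl = slice(start, min(start + chunk, p))
        blk = X[sl]
        diff = (blk[:, :, None] - blk[:, None, :]) / h[sl, None, None]
        Z[sl] = ndtr(diff).mean(axis=2)
    Z[const] = 0.5
    return pd.DataFrame(Z, index=expr.index, columns=expr.columns)


@dataclass
class RankStats:
    """Per-sample gene ordering and symmetric rank statistic.

    order[i, s] is the index (into ``genes``) of the gene at rank i+1
    (rank 1 = largest z) in sample s; ``r_sorted[i, s]`` is the symmetric
    rank statistic |p/2 - (i+1)| shared by all samples; ``ranks`` maps
    each gene to its rank per sample.
    """

    genes: pd.Index
    samples: pd.Index
    order: np.ndarray  # (p, n) int
    ranks: pd.DataFrame  # (p, n) rank of each gene, 1..p

    @property
    def p(self) -> int:
        return len(self.genes)

    def r_values(self) -> pd.DataFrame:
        """Symmetric rank statistic per gene and sample."""
        return (self.p / 2.0 - self.ranks).abs()


def symmetric_ranks(zmat: pd.DataFrame) -> RankStats:
    """Rank genes by z descending within each sample (ties by gene id)."""
    p, n = zmat.shape
    Z = zmat.to_numpy(dtype=float)
    gene_ids = zmat.index.to_numpy(dtype=object).astype(str)
    order = np.empty((p, n), dtype=np.int64)
    ranks = np.empty((p, n), dtype=np.int64)
    for s in range(n):
        # np.lexsort: last key is primary; ascending -z = descending z,
        # gene id lexicographic breaks ties deterministically.
        o = np.lexsort((gene_ids, -Z[:, s]))
        order[:, s] = o
        ranks[o, s] = np.arange(1, p + 1)
    return RankStats(
        genes=zmat.index,
        samples=zmat.columns,
        order=order,
        ranks=pd.DataFrame(ranks, index=zmat.index, columns=zmat.columns),
    )


def walk_score(
    rank_stats: RankStats,
    set_genes: Sequence[str],
    cfg: WalkConfig | None = None,
) -> pd.Series:
    """Weighted Kolmogorov–Smirnov-like walk score of one set per sample."""
    cfg = cfg or WalkConfig()
    p = rank_stats.p
    idx = {g: i for i, g in enumerate(rank_stats.genes)}
    members = np.zeros(p, dtype=bool)
    hit = 0
    for g in set_genes:
        if g in idx:
            members[idx[g]] = True
            hit += 1
    m = int(members.sum())
    if m == 0:
        raise ValueError("gene set has empty intersection with the universe")
    if m == p:
        raise ValueError("gene set equals the whole universe; outside-set step undefined")

    order = rank_stats.order  # (p, n)
    n = order.shape[1]
    # symmetric rank statistic along the walk is the same profile for
    # every sample: |p/2 - i| for rank i = 1..p
    r_profile = np.abs(p / 2.0 - np.arange(1, p + 1, dtype=float))
    M = members[order]  # (p, n) in-set indicator in walk order
    W = (r_profile[:, None] ** cfg.tau) * M
    denom = W.sum(axis=0)
    # all in-set genes exactly at the rank center (r = 0): fall back to
    # unweighted steps so the walk is still defined
    zero = denom == 0
    if zero.any():
        W[:, zero] = M[:, zero].astype(float)
        denom[zero] = m
    steps = W / denom - (~M) / float(p - m)
    walk = np.cumsum(steps, axis=0)
    vmax = walk.max(axis=0)
    vmin = walk.min(axis=0)
    if cfg.score_mode == "max_diff":
        score = np.maximum(vmax, 0.0) + np.minimum(vmin, 0.0)
    else:  # max_abs
        score = np.where(vmax >= -vmin, vmax, vmin)
    return pd.Series(score, index=rank_stats.samples)


def score_catalog(
    expr: pd.DataFrame,
    catalog: MarkerCatalog,
    cfg: WalkConfig | None = None,
    delim: str = DEFAULT_DELIM,
) -> pd.DataFrame:
    """Enrichment-score matrix (marker sets x samples) for a whole catalog.

    The kernel CDF and ranking are computed once; each of the catalog's
    sets is then walked.  Row order follows the catalog.  The catalog
    should already be restricted to the measured universe
    (:func:`gczoner.catalog.restrict_to_universe`).
    """
    cfg = cfg or WalkConfig()
    z = kernel_cdf(expr, kernel=cfg.kernel)
    rs = symmetric_ranks(z)
    rows = []
    names = []
    for s in catalog.sets:
        rows.append(walk_score(rs, s.genes, cfg))
        names.append(s.name(delim))
    es = pd.DataFrame(rows, index=names)
    es.index.name = "set"
    return es
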