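"""Group-level dominance statistics for GC substages.

For every (group, substage) pair, samples are cross-classified as
in-group vs out-of-group and dominant-for-the-substage vs not, giving a
2x2 table tested with Fisher's exact test (one-sided "greater" by
default, since dominance is directional).  P-values are
Benjamini-Hochberg adjusted across all (group x substage) tests jointly.
Cohen's d on the substage's differential enrichment scores (in-group vs
all other samples) gates significance by effect size: a substage is
flagged dominant in a group when adj_p < alpha AND |d| >= the gate
(default 0.3, medium-or-larger).
"""

from __future__ import annotations

from math import comb, inf, isfinite, sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import UNASSIGNED

EFFECT_SMALL_MAX = 0.3   # |d| <= 0.3 -> small
EFFECT_LARGE_MIN = 0.5   # |d| >= 0.5 -> large (boundary assigned to large)


def fisher_exact(a: int, b: int, c: int, d: int, sided: str = "greater") -> float:
    """Fisher's exact p-value for a 2x2 table by hypergeometric enumeration.

    Table layout: rows = in-group / out-of-group, columns = dominant /
    not-dominant, i.e. ``a`` in-group dominant, ``b`` in-group not,
    ``c`` out-group dominant, ``d`` out-group not.  One-sided "greater"
    sums P[A >= a] under fixed margins; "two_sided" sums all tables with
    point probability <= the observed one.  No normal approximation.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    if sided not in ("greater", "two_sided"):
        raise ValueError(f"unknown sidedness {sided!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + c   # dominant total
    n = a + b   # group size
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        return 1.0  # degenerate margin: only one table possible
    lo = max(0, n - (N - K))
    hi = min(n, K)
    denom = comb(N, n)
    pmf = {x: comb(K, x) * comb(N - K, n - x) / denom for x in range(lo, hi + 1)}
    if sided == "greater":
        return min(1.0, sum(p for x, p in pmf.items() if x >= a))
    obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= obs * (1 + 1e-7)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference with pooled-SD denominator.

    d = (mean(x) - mean(y)) / s_pooled with
    s_pooled^2 = ((n_x-1)s_x^2 + (n_y-1)s_y^2) / (n_x + n_y - 2).
    Zero pooled variance: returns 0 for equal means, signed infinity
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("cohens_d needs at least 2 observations per group")
    nx, ny = x.size, y.size
    num = x.mean() - y.mean()
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0 if num == 0 else (inf if num > 0 else -inf)
    return float(num / sqrt(sp2))


def classify_effect(d: float) -> str:
    """Cohen's classes: small (|d| <= 0.3), medium (0.3 < |d| < 0.5),
    large (|d| >= 0.5; the 0.5 boundary is assigned to large)."""
    if not isfinite(d):
        raise ValueError("effect size must be finite")
    ad = abs(d)
    if ad <= EFFECT_SMALL_MAX:
        return "small"
    if ad < EFFECT_LARGE_MIN:
        return "medium"
    return "large"


def zone_tests(
    calls: pd.DataFrame,
    diff: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    effect_gate: float = EFFECT_SMALL_MAX,
    sided: str = "greater",
) -> pd.DataFrame:
    """Dominance tests for every (group, substage) pair.

    Unassigned samples count as not-dominant for every substage.  Groups
    with fewer than 2 samples on either side of a comparison get an
    undefined (NaN) effect size; their Fisher test still runs but they
    can never be flagged.  Emits ``neglog10_adj_p`` for plotting against
    the 1.3 reference line (= -log10 0.05).

    Returns a DataFrame with columns group, substage, a, b, c, d,
    fisher_p, adj_p, neglog10_adj_p, cohens_d, effect_class,
    dominant_flag.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = [s for s in calls.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    samples = list(calls.index)
    group_of = meta.loc[samples, "group"]
    groups = list(dict.fromkeys(group_of))
    if len(groups) < 2:
        raise ValueError("zone_tests needs at least 2 groups")
    substages = list(diff.index)

    records = []
    for g in groups:
        in_g = group_of == g
        in_ids = [s for s, f in zip(samples, in_g) if f]
        out_ids = [s for s, f in zip(samples, in_g) if not f]
        for sub in substages:
            dom = calls["dominant"] == sub
            a = int(dom.loc[in_ids].sum())
            b = len(in_ids) - a
            c = int(dom.loc[out_ids].sum())
            dd = len(out_ids) - c
            p = fisher_exact(a, b, c, dd, sided=sided)
            if len(in_ids) >= 2 and len(out_ids) >= 2:
                d_eff = cohens_d(
                    diff.loc[sub, in_ids].to_numpy(),
                    diff.loc[sub, out_ids].to_numpy(),
                )
                eff_class = classify_effect(d_eff) if isfinite(d_eff) else "large"
            else:
                d_eff = float("nan")
                eff_class = "undefined"
            records.append((g, sub, a, b, c, dd, p, d_eff, eff_class))

    tab = pd.DataFrame(
        records,
        columns=["group", "substage", "a", "b", "c", "d", "fisher_p", "cohens_d", "effect_class"],
    )
    tab["adj_p"] = bh_adjust(tab["fisher_p"].to_numpy())
    tab["neglog10_adj_p"] = -np.log10(tab["adj_p"])
    with np.errstate(invalid="ignore"):
        tab["dominant_flag"] = (tab["adj_p"] < alpha) & (
            tab["cohens_d"].abs() >= effect_gate
        )
    cols = [
        "group", "substage", "a", "b", "c", "d", "fisher_p", "adj_p",
        "neglog10_adj_p", "cohens_d", "effect_class", "dominant_flag",
    ]
    return tab[cols]
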