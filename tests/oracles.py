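"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the statistics by the most literal route
possible (double loops, step-by-step walks, exact rational hypergeometric
enumeration) and share no code with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import norm


def brute_kernel_cdf(X: np.ndarray) -> np.ndarray:
    """Double-loop Gaussian-kernel CDF, bandwidth sd/4 per gene."""
    p, n = X.shape
    Z = np.zeros((p, n))
    for g in range(p):
        sd = np.std(X[g], ddof=1)
        if sd == 0:
            Z[g] = 0.5
            continue
        h = sd / 4.0
        for s in range(n):
            acc = 0.0
            for k in range(n):
                acc += norm.cdf((X[g, s] - X[g, k]) / h)
            Z[g, s] = acc / n
    return Z


def brute_walk(
    order: list[int], members: set[int], tau: float, score_mode: str
) -> float:
    """Step-by-step random walk over one sample's gene ordering.

    ``order`` lists gene indices from rank 1 (largest) to rank p;
    ``members`` holds the in-set gene indices.
    """
    p = len(order)
    m = len(members & set(order))
    r = [abs(p / 2.0 - (i + 1)) for i in range(p)]
    denom = sum(r[i] ** tau for i, g in enumerate(order) if g in members)
    level = 0.0
    dev_max, dev_min = -np.inf, np.inf
    for i, g in enumerate(order):
        if g in members:
            level += (r[i] ** tau) / denom if denom > 0 else 1.0 / m
        else:
            level -= 1.0 / (p - m)
        dev_max = max(dev_max, level)
        dev_min = min(dev_min, level)
    if score_mode == "max_diff":
        return max(dev_max, 0.0) + min(dev_min, 0.0)
    return dev_max if dev_max >= -dev_min else dev_min


def brute_fisher(a: int, b: int, c: int, d: int, sided: str) -> float:
    """Exact-rational enumeration of all 2x2 tables with the observed margins."""
    N, K, n = a + b + c + d, a + c, a + b
    if N == 0 or K in (0, N) or n in (0, N):
        return 1.0
    lo, hi = max(0, n - (N - K)), min(n, K)
    denom = comb(N, n)
    probs = {x: Fraction(comb(K, x) * comb(N - K, n - x), denom) for x in range(lo, hi + 1)}
    if sided == "greater":
        return float(sum(p for x, p in probs.items() if x >= a))
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


def brute_bh(pvals: list[float]) -> list[float]:
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(pvals)
    idx = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    for i in range(m):
        q_sorted[i] = min(min(pvals[idx[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    out = [0.0] * m
    for i in range(m):
        out[idx[i]] = q_sorted[i]
    return out
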