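"""Exact combinatorial test statistics.

All probabilities here are computed with integer arithmetic (``math.comb``)
and divided once at the end, so results are exact up to one floating-point
rounding and never depend on summation order or library tolerances.
"""

from __future__ import annotations

import math
from typing import Sequence, Tuple

__all__ = [
    "hypergeom_tail",
    "fisher_exact_two_sided",
    "binom_two_sided_half",
    "bh_adjust",
]


def hypergeom_tail(k_major: int, K: int, n_major: int, n_minor: int) -> float:
    """Upper-tail hypergeometric probability.

    Probability that, distributing ``K`` carriers uniformly at random among
    ``n_major + n_minor`` samples, the majority group of size ``n_major``
    receives at least ``k_major`` of them:

        sum_{j >= k_major} C(n_major, j) C(n_minor, K - j) / C(n_major + n_minor, K)
    """
    if n_major < 0 or n_minor < 0:
        raise ValueError("group sizes must be non-negative")
    if not 0 <= K <= n_major + n_minor:
        raise ValueError(f"impossible carrier total K={K} for {n_major}+{n_minor} samples")
    if not 0 <= k_major <= min(K, n_major):
        raise ValueError(f"impossible majority count k={k_major} (K={K}, n_major={n_major})")
    if K - k_major > n_minor:
        raise ValueError(f"impossible counts: K-k={K - k_major} carriers exceed n_minor={n_minor}")
    total = math.comb(n_major + n_minor, K)
    num = sum(
        math.comb(n_major, j) * math.comb(n_minor, K - j)
        for j in range(k_major, min(K, n_major) + 1)
    )
    return num / total


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher exact test by the minimum-likelihood summation rule.

    Returns ``(odds_ratio, p)`` where the p-value sums, over all 2x2 tables
    with the observed margins, the probabilities of tables no more likely
    than the observed one. The comparison is done on exact integer weights,
    so there is no tie-breaking tolerance. The odds ratio is the sample
    (unconditional) estimate a*d / (b*c).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return math.nan, 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    p = sum(w for w in weights if w <= obs) / math.comb(n, c1)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return odds, min(p, 1.0)


def binom_two_sided_half(k: int, n: int) -> float:
    """Exact two-sided binomial test with success probability 1/2.

    p = 2 * min(P(X <= k), P(X >= k)) capped at 1, with X ~ Binomial(n, 1/2).
    """
    if n <= 0:
        raise ValueError("binomial test undefined for n <= 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    total = 1 << n
    lower = sum(math.comb(n, j) for j in range(0, k + 1))
    upper = sum(math.comb(n, j) for j in range(k, n + 1))
    return min(1.0, 2 * min(lower, upper) / total)


def bh_adjust(pvals: Sequence[float]) -> list:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(pvals)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
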