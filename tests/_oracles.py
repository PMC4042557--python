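"""Independent brute-force oracles used to check the package implementations.

These stay deliberately naive: exhaustive enumeration, all-pairs scans, and
exact rational arithmetic. None of them share code with the package paths
they verify.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from typing import List, Sequence, Tuple


def window_caller(
    ratios: Sequence[float],
    region_ids: Sequence[object],
    tau: float,
    min_probes: int,
) -> List[Tuple[int, int, int]]:
    """All maximal same-sign threshold windows, by testing every window.

    Returns (start_index, stop_index_exclusive, sign) for every contiguous
    window within one region whose values all exceed +tau or all fall below
    -tau, that cannot be extended in either direction, and that spans at
    least ``min_probes`` probes.
    """
    n = len(ratios)

    def cond(i, j, s):  # all probes in [i, j) strictly beyond the threshold, sign s
        if len({region_ids[k] for k in range(i, j)}) != 1:
            return False
        return all(s * ratios[k] > tau for k in range(i, j))

    out = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            for s in (1, -1):
                if not cond(i, j, s):
                    continue
                left_ext = i > 0 and cond(i - 1, j, s)
                right_ext = j < n and cond(i, j + 1, s)
                if not left_ext and not right_ext and (j - i) >= min_probes:
                    out.append((i, j, s))
    return sorted(set(out))


def hypergeom_by_enumeration(k_major: int, K: int, n1: int, n2: int) -> Fraction:
    """P(majority group holds >= k_major carriers) by listing every
    assignment of K carriers to n1+n2 labelled samples."""
    samples = range(n1 + n2)
    major = set(range(n1))
    hits = total = 0
    for carriers in itertools.combinations(samples, K):
        total += 1
        if len(major.intersection(carriers)) >= k_major:
            hits += 1
    return Fraction(hits, total)


def fisher_two_sided_by_enumeration(table) -> Fraction:
    """Minimum-likelihood two-sided Fisher p with exact rational table
    probabilities P = r1! r2! c1! c2! / (n! a! b! c! d!)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    c2 = b + d
    n = r1 + r2

    def prob(x):
        bb, cc, dd = r1 - x, c1 - x, r2 - (c1 - x)
        if min(bb, cc, dd) < 0:
            return None
        num = (
            math.factorial(r1) * math.factorial(r2) * math.factorial(c1) * math.factorial(c2)
        )
        den = (
            math.factorial(n) * math.factorial(x) * math.factorial(bb)
            * math.factorial(cc) * math.factorial(dd)
        )
        return Fraction(num, den)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p is not None and p <= p_obs:
            total += p
    return total


def binom_two_sided_by_enumeration(k: int, n: int) -> Fraction:
    """2 * min(P(X<=k), P(X>=k)) for X ~ Binomial(n, 1/2), exact."""
    denom = Fraction(2) ** n
    lower = sum(math.comb(n, j) for j in range(0, k + 1)) / denom
    upper = sum(math.comb(n, j) for j in range(k, n + 1)) / denom
    return min(Fraction(1), 2 * min(lower, upper))


def all_pairs_overlaps(cnvs, features, min_frac):
    """Naive O(n*m) intersection keeping the fraction-of-CNV rule."""
    out = []
    for c in cnvs:
        for f in features:
            if c.chrom != f.chrom:
                continue
            ov = min(c.end, f.end) - max(c.start, f.start)
            if ov > 0 and ov / (c.end - c.start) >= min_frac:
                out.append((c.cnv_id, f, ov))
    return out


def cluster_by_union_find(items):
    """Transitive closure of >= 1 bp interval overlap among (start, end) pairs.

    Returns a list of frozensets of item indices.
    """
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            si, ei = items[i]
            sj, ej = items[j]
            if si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def spearman_by_ranks(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of average ranks, computed from first principles."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
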