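"""Cross-sample CNV loci and population-differentiation flagging.

Same-sign calls on one chromosome that overlap by at least 1 bp are merged
into loci by single-linkage clustering. A locus differentiates the two
populations when one population contributes at least ``min_major`` carriers,
the other at most ``max_minor``, and the one-tailed hypergeometric
probability of a split at least that skewed is below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from ._exact import bh_adjust, hypergeom_tail
from .calling import CnvCall

__all__ = [
    "CnvLocus",
    "DifferentiationResult",
    "cluster_calls",
    "hypergeom_p",
    "flag_differentiating",
]


@dataclass
class CnvLocus:
    locus_id: str
    chrom: str
    footprint_start: int
    footprint_end: int
    sign: str
    populations: Tuple[str, str]
    carriers: Tuple[int, int]  # distinct carrier samples per population
    pop_sizes: Tuple[int, int]
    member_calls: List[CnvCall]

    def __post_init__(self):
        for k, n in zip(self.carriers, self.pop_sizes):
            if not 0 <= k <= n:
                raise ValueError(f"carrier count {k} outside [0, {n}]")


@dataclass
class DifferentiationResult:
    locus_id: str
    p_hypergeom: float
    p_bh: float  # BH-adjusted, diagnostic only; never used for the flag
    is_differentiating: bool
    major_population: Optional[str]


def cluster_calls(
    all_calls: Sequence[CnvCall],
    pop_of: Mapping[str, str],
    populations: Optional[Tuple[str, str]] = None,
    pop_sizes: Optional[Mapping[str, int]] = None,
) -> List[CnvLocus]:
    """Single-linkage clustering of same-sign, same-chromosome calls.

    Two calls join a locus when their half-open intervals share >= 1 bp,
    directly or through a chain of overlapping calls. Each sample
    contributes at most one carrier flag per locus.
    """
    if populations is None:
        pops = tuple(sorted(set(pop_of.values())))
    else:
        pops = tuple(populations)
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    if pop_sizes is None:
        sizes = {p: sum(1 for v in pop_of.values() if v == p) for p in pops}
    else:
        sizes = dict(pop_sizes)

    clusters: List[List[CnvCall]] = []
    for (chrom, sign), group in _group_by_chrom_sign(all_calls):
        group = sorted(group, key=lambda c: (c.start, c.end))
        current: List[CnvCall] = []
        cur_end = None
        for call in group:
            if current and call.start < cur_end:  # >=1 bp overlap, half-open
                current.append(call)
                cur_end = max(cur_end, call.end)
            else:
                if current:
                    clusters.append(current)
                current = [call]
                cur_end = call.end
        if current:
            clusters.append(current)

    clusters.sort(key=lambda cl: (cl[0].chrom, min(c.start for c in cl), cl[0].sign))
    loci = []
    for i, members in enumerate(clusters):
        carriers = {p: set() for p in pops}
        for c in members:
            pop = pop_of[c.sample_id]
            carriers[pop].add(c.sample_id)
        loci.append(
            CnvLocus(
                locus_id=f"locus_{i + 1:04d}",
                chrom=members[0].chrom,
                footprint_start=min(c.start for c in members),
                footprint_end=max(c.end for c in members),
                sign=members[0].sign,
                populations=pops,
                carriers=(len(carriers[pops[0]]), len(carriers[pops[1]])),
                pop_sizes=(sizes[pops[0]], sizes[pops[1]]),
                member_calls=list(members),
            )
        )
    return loci


def _group_by_chrom_sign(calls: Sequence[CnvCall]):
    groups: Dict[Tuple[str, str], List[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.chrom, c.sign), []).append(c)
    return sorted(groups.items())


def hypergeom_p(k_major: int, K: int, n1: int, n2: int) -> float:
    """One-tailed hypergeometric p toward the majority population.

    ``n1`` is the majority population's sample size. Probability that a
    uniform distribution of the ``K`` carriers over ``n1 + n2`` samples
    places at least ``k_major`` of them in the majority population.
    """
    return hypergeom_tail(k_major, K, n1, n2)


def flag_differentiating(
    loci: Sequence[CnvLocus],
    alpha: float = 0.05,
    min_major: int = 4,
    max_minor: int = 1,
) -> List[DifferentiationResult]:
    """Apply the carrier-count rule plus hypergeometric test per locus.

    A locus is flagged iff max(k1, k2) >= min_major, min(k1, k2) <=
    max_minor, and the one-tailed hypergeometric p is below alpha. Ties
    (k1 == k2) never satisfy both count conditions when min_major >
    max_minor, so they are never flagged. BH-adjusted p-values are emitted
    as a diagnostic column only.
    """
    raw: List[float] = []
    partial = []
    for locus in loci:
        k1, k2 = locus.carriers
        n1, n2 = locus.pop_sizes
        if k1 >= k2:
            k_major, n_major, n_minor = k1, n1, n2
            major_pop = locus.populations[0]
        else:
            k_major, n_major, n_minor = k2, n2, n1
            major_pop = locus.populations[1]
        p = hypergeom_p(k_major, k1 + k2, n_major, n_minor)
        flagged = max(k1, k2) >= min_major and min(k1, k2) <= max_minor and p < alpha
        raw.append(p)
        partial.append((locus.locus_id, p, flagged, major_pop if k1 != k2 else None))
    adjusted = bh_adjust(raw)
    return [
        DifferentiationResult(lid, p, p_bh, flagged, major)
        for (lid, p, flagged, major), p_bh in zip(partial, adjusted)
    ]
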