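"""Interval intersection of CNVs with gene features.

Coordinates are 0-based half-open throughout. A (CNV, feature) pair is
reported only when the intersection covers at least ``min_frac_of_cnv`` of
the CNV's length (default 10%). Strand is ignored.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

FEATURE_CLASSES = ("intron", "exon", "exon3", "exon5")


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    gene_id: str
    feature_class: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"feature {self.gene_id}: start {self.start} >= end {self.end}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvInterval:
    """Minimal CNV view for overlap work; build from calls or loci."""

    cnv_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"CNV {self.cnv_id}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapRecord:
    cnv_id: str
    feature: Feature
    overlap_bp: int
    fraction_of_cnv: float
    fraction_of_feature: float


def intersect(
    cnvs: Sequence[CnvInterval],
    features: Sequence[Feature],
    min_frac_of_cnv: float = 0.10,
) -> List[OverlapRecord]:
    """All (CNV, feature) intersections meeting the fraction-of-CNV rule.

    Sweep-line over start-sorted intervals per chromosome with an active
    heap keyed by feature end; O((n+m) log m + output).
    """
    if not 0 <= min_frac_of_cnv <= 1:
        raise ValueError("min_frac_of_cnv must lie in [0, 1]")
    feats_by_chrom: Dict[str, List[Feature]] = {}
    for f in features:
        feats_by_chrom.setdefault(f.chrom, []).append(f)
    for fs in feats_by_chrom.values():
        fs.sort(key=lambda f: (f.start, f.end))
    cnvs_by_chrom: Dict[str, List[CnvInterval]] = {}
    for c in cnvs:
        cnvs_by_chrom.setdefault(c.chrom, []).append(c)

    records: List[OverlapRecord] = []
    for chrom, cs in sorted(cnvs_by_chrom.items()):
        cs.sort(key=lambda c: (c.start, c.end))
        fs = feats_by_chrom.get(chrom, [])
        active: List[Tuple[int, int, Feature]] = []  # (end, tiebreak, feature)
        fi = 0
        for cnv in cs:
            while fi < len(fs) and fs[fi].start < cnv.end:
                heapq.heappush(active, (fs[fi].end, fi, fs[fi]))
                fi += 1
            while active and active[0][0] <= cnv.start:
                heapq.heappop(active)
            for _, _, feat in active:
                ov = min(cnv.end, feat.end) - max(cnv.start, feat.start)
                if ov <= 0:
                    continue  # pushed for a later cnv on this chrom
                frac_cnv = ov / cnv.length
                if frac_cnv >= min_frac_of_cnv and frac_cnv > 0:
                    records.append(
                        OverlapRecord(
                            cnv_id=cnv.cnv_id,
                            feature=feat,
                            overlap_bp=ov,
                            fraction_of_cnv=frac_cnv,
                            fraction_of_feature=ov / feat.length,
                        )
                    )
    records.sort(key=lambda r: (r.feature.chrom, r.feature.start, r.cnv_id))
    return records


def class_shares(element_counts: Mapping[str, int]) -> Dict[str, float]:
    """Fraction of elements per feature class; shares sum to 1."""
    total = sum(element_counts.values())
    if total == 0:
        return {c: 0.0 for c in element_counts}
    return {c: n / total for c, n in element_counts.items()}


@dataclass
class OverlapSummary:
    element_counts: Dict[str, int]  # distinct features hit, per class
    shares: Dict[str, float]
    n_genes: int
    median_fraction_of_feature: Dict[str, Optional[float]]

    @property
    def n_elements(self) -> int:
        return sum(self.element_counts.values())


def summarize_overlaps(records: Sequence[OverlapRecord]) -> OverlapSummary:
    """Element counts, class shares, affected genes, median feature fractions.

    An element is a distinct feature hit by at least one record; a gene is
    counted once however many of its elements are hit. Median fractions are
    taken over records within each class. Empty input yields zero counts
    with medians flagged undefined (``None``).
    """
    elements = {c: set() for c in FEATURE_CLASSES}
    fractions: Dict[str, List[float]] = {c: [] for c in FEATURE_CLASSES}
    genes = set()
    for r in records:
        elements[r.feature.feature_class].add(r.feature)
        fractions[r.feature.feature_class].append(r.fraction_of_feature)
        genes.add(r.feature.gene_id)
    counts = {c: len(s) for c, s in elements.items()}
    medians = {
        c: (float(np.median(v)) if v else None) for c, v in fractions.items()
    }
    return OverlapSummary(
        element_counts=counts,
        shares=class_shares(counts),
        n_genes=len(genes),
        median_fraction_of_feature=medians,
    )
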