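"""Association between CNVs and gene-expression differentiation.

Three analyses: Spearman correlation of per-gene CNV size against
expression statistics, Fisher-exact enrichment of CNV genes among
differentially-expressed (DE) versus invariant genes, and the direction
concordance of differentiating loci with expression change, tested with an
exact two-sided binomial test at success probability 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _st

from ._exact import binom_two_sided_half, fisher_exact_two_sided

TISSUES = ("brain", "liver", "testis")
PLATFORMS = ("A", "B")
CATEGORIES = ("expected", "opposite", "no_change", "opposing_tissues")

EXPRESSION_COLUMNS = ["gene_id", "tissue", "platform", "p_value", "t_statistic", "status"]


def correlate_cnv_expression(
    cnv_sizes: Mapping[str, float],
    stats: pd.DataFrame,
    tissue: str,
    platform: str,
    value: str = "p_value",
    include_non_cnv: bool = True,
) -> Tuple[float, float]:
    """Spearman correlation between per-gene CNV size and an expression column.

    Genes without a CNV enter with size 0 when ``include_non_cnv`` is set
    (default), so the correlation runs over the whole tested gene panel;
    otherwise only CNV-carrying genes are used. Ties get average ranks and
    the two-sided p uses the t approximation. Returns ``(rho, p)``;
    a constant vector yields ``(nan, nan)``.
    """
    sub = stats[(stats["tissue"] == tissue) & (stats["platform"] == platform)]
    if not include_non_cnv:
        sub = sub[sub["gene_id"].isin(cnv_sizes)]
    x = np.array([float(cnv_sizes.get(g, 0.0)) for g in sub["gene_id"]])
    y = sub[value].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 genes with both a CNV size and a statistic")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    res = _st.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def de_enrichment(
    n_cnv_in_de: int, n_de: int, n_cnv_in_inv: int, n_inv: int
) -> Tuple[List[List[int]], float, float]:
    """2x2 CNV-carrier enrichment among DE versus invariant genes.

    Returns ``(table, two_sided_fisher_p, odds_ratio)`` with the table
    ``[[cnv_de, de - cnv_de], [cnv_inv, inv - cnv_inv]]``. The two-sided p
    sums the probabilities of tables no more likely than the observed one
    (minimum-likelihood rule, exact integer arithmetic).
    """
    if min(n_cnv_in_de, n_de, n_cnv_in_inv, n_inv) < 0:
        raise ValueError("counts must be non-negative")
    if n_cnv_in_de > n_de or n_cnv_in_inv > n_inv:
        raise ValueError("CNV-carrier count exceeds its group size")
    table = [[n_cnv_in_de, n_de - n_cnv_in_de], [n_cnv_in_inv, n_inv - n_cnv_in_inv]]
    odds, p = fisher_exact_two_sided(table)
    return table, p, odds


@dataclass
class ConcordanceRecord:
    locus_id: str
    cnv_sign: str  # "amplification" | "deletion"
    expression_direction: str  # up | down | none | mixed
    category: str  # expected | opposite | no_change | opposing_tissues

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_locus(
    locus_id: str,
    cnv_sign: str,
    gene_stats: pd.DataFrame,
) -> ConcordanceRecord:
    """Map one differentiating locus to an expression-direction category.

    Among the locus's genes, only rows with status ``DE`` carry direction.
    The gene with the smallest DE p-value decides; if that gene's DE rows
    disagree in t-statistic sign across tissues, or distinct genes tie on
    the minimum p-value with conflicting directions, the direction is
    ``mixed`` (category ``opposing_tissues``). No DE rows at all means
    ``none`` (category ``no_change``).
    """
    de = gene_stats[gene_stats["status"] == "DE"]
    if len(de) == 0:
        return ConcordanceRecord(locus_id, cnv_sign, "none", "no_change")
    pmin = de["p_value"].min()
    best_genes = de[de["p_value"] == pmin]["gene_id"].unique()
    rows = de[de["gene_id"].isin(best_genes)]
    signs = set(np.sign(rows["t_statistic"].to_numpy(float)))
    signs.discard(0.0)
    if len(signs) != 1:
        return ConcordanceRecord(locus_id, cnv_sign, "mixed", "opposing_tissues")
    direction = "up" if signs.pop() > 0 else "down"
    expected = (cnv_sign == "amplification" and direction == "up") or (
        cnv_sign == "deletion" and direction == "down"
    )
    return ConcordanceRecord(locus_id, cnv_sign, direction, "expected" if expected else "opposite")


@dataclass
class ConcordanceReport:
    counts: Dict[str, int]
    total: int
    p_binomial: Optional[float]  # None when expected + opposite == 0

    @property
    def defined(self) -> bool:
        return self.p_binomial is not None


def concordance_report(
    n_expected: int,
    n_opposite: int,
    n_no_change: int = 0,
    n_opposing_tissues: int = 0,
) -> ConcordanceReport:
    """Totals plus exact two-sided binomial test on expected vs opposite.

    p = 2 * min(P(X <= k), P(X >= k)) with X ~ Binomial(expected+opposite,
    1/2) and k = expected, capped at 1. Undefined (None) when there are no
    directional loci.
    """
    counts = {
        "expected": int(n_expected),
        "opposite": int(n_opposite),
        "no_change": int(n_no_change),
        "opposing_tissues": int(n_opposing_tissues),
    }
    if min(counts.values()) < 0:
        raise ValueError("category counts must be non-negative")
    n = n_expected + n_opposite
    p = binom_two_sided_half(n_expected, n) if n > 0 else None
    return ConcordanceReport(counts=counts, total=sum(counts.values()), p_binomial=p)


def direction_concordance(records: Sequence[ConcordanceRecord]) -> ConcordanceReport:
    """Aggregate per-locus records into the concordance report."""
    c = {cat: 0 for cat in CATEGORIES}
    for r in records:
        c[r.category] += 1
    return concordance_report(c["expected"], c["opposite"], c["no_change"], c["opposing_tissues"])
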