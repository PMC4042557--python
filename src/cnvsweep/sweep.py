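"""Microsatellite heterozygosity sweep scan (lnRH).

Per locus and population, expected heterozygosity H is estimated from
allele frequencies with the unbiased 2n/(2n-1) correction. Under the
stepwise mutation model theta = 0.5 * ((1/(1-H))^2 - 1); lnRH is the log
ratio of theta between the two populations. Candidate lnRH values are
standardized against a neutral-locus panel, and |z| > 2 flags a locus.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPE_COLUMNS = ["locus", "population", "individual", "allele1_bp", "allele2_bp", "panel"]


@dataclass
class MicrosatLocus:
    locus_id: str
    population: str
    genotypes: List[Tuple[int, int]]  # diploid allele lengths, bp
    panel: str = "neutral"  # "neutral" | "candidate"

    def __post_init__(self):
        if self.panel not in ("neutral", "candidate"):
            raise ValueError(f"unknown panel {self.panel!r}")


def expected_heterozygosity(genotypes: Sequence[Tuple[int, int]]) -> Optional[float]:
    """Unbiased gene diversity H = (2n/(2n-1)) * (1 - sum p_i^2).

    Genotypes with a missing allele (None/NaN) are dropped. A monomorphic
    locus is corrected as if exactly one of the 2n allele copies differed,
    so H (and hence theta) never collapses to zero. Returns None when no
    genotypes remain; raises for n < 2 (the correction is undefined).
    """
    clean = [
        (a, b)
        for a, b in genotypes
        if a is not None and b is not None and not (isinstance(a, float) and math.isnan(a))
        and not (isinstance(b, float) and math.isnan(b))
    ]
    if not clean:
        return None
    n = len(clean)
    if n < 2:
        raise ValueError("expected heterozygosity requires >= 2 genotyped individuals")
    two_n = 2 * n
    counts = Counter()
    for a, b in clean:
        counts[a] += 1
        counts[b] += 1
    if len(counts) == 1:
        # monomorphic correction: one of the 2n copies treated as distinct
        freqs = [(two_n - 1) / two_n, 1 / two_n]
    else:
        freqs = [c / two_n for c in counts.values()]
    return (two_n / (two_n - 1)) * (1.0 - sum(f * f for f in freqs))


def theta_from_h(h: float) -> float:
    """Stepwise-mutation-model theta: 0.5 * ((1/(1-H))^2 - 1)."""
    if not 0 <= h < 1:
        raise ValueError(f"H={h} outside [0, 1)")
    return 0.5 * ((1.0 / (1.0 - h)) ** 2 - 1.0)


def lnrh(h1: float, h2: float) -> float:
    """ln(theta1 / theta2); antisymmetric under swapping the populations."""
    t1, t2 = theta_from_h(h1), theta_from_h(h2)
    if t1 == 0 or t2 == 0:
        raise ValueError("theta = 0 (H = 0); apply the monomorphic correction upstream")
    return math.log(t1 / t2)


@dataclass
class LnRHResult:
    locus_id: str
    panel: str
    h_pop1: float
    h_pop2: float
    theta1: float
    theta2: float
    lnrh: float
    z: Optional[float] = None
    flagged: bool = False


def standardize(results: Sequence[LnRHResult], z_cutoff: float = 2.0) -> List[LnRHResult]:
    """Standardize lnRH against the neutral panel: z = (x - mean)/sd (ddof 1).

    Requires >= 2 finite neutral lnRH values with non-zero spread; flags
    |z| > z_cutoff. Neutral loci receive z values too, for diagnostics.
    """
    neutral = [r.lnrh for r in results if r.panel == "neutral" and math.isfinite(r.lnrh)]
    if len(neutral) < 2:
        raise ValueError("neutral panel must contain >= 2 finite lnRH values")
    mean = float(np.mean(neutral))
    sd = float(np.std(neutral, ddof=1))
    if sd == 0:
        raise ValueError("neutral panel lnRH has zero spread; cannot standardize")
    out = []
    for r in results:
        z = (r.lnrh - mean) / sd
        out.append(
            LnRHResult(
                r.locus_id, r.panel, r.h_pop1, r.h_pop2, r.theta1, r.theta2, r.lnrh,
                z=z, flagged=abs(z) > z_cutoff,
            )
        )
    return out


def scan(
    genotypes: pd.DataFrame,
    numerator_population: str,
    z_cutoff: float = 2.0,
) -> List[LnRHResult]:
    """Full lnRH scan from a long genotype table.

    ``genotypes`` columns: locus, population, individual, allele1_bp,
    allele2_bp, panel. ``numerator_population`` fixes which population's
    theta is the lnRH numerator (pop1 in the output).
    """
    pops = sorted(genotypes["population"].unique())
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    if numerator_population not in pops:
        raise ValueError(f"numerator population {numerator_population!r} not in {pops}")
    pop1 = numerator_population
    pop2 = [p for p in pops if p != pop1][0]

    results = []
    for locus, g in genotypes.groupby("locus", sort=True):
        panels = g["panel"].unique()
        if len(panels) != 1:
            raise ValueError(f"locus {locus}: inconsistent panel labels {panels}")
        hs = {}
        for pop in (pop1, pop2):
            gt = g[g["population"] == pop]
            pairs = list(zip(gt["allele1_bp"], gt["allele2_bp"]))
            h = expected_heterozygosity(pairs)
            if h is None:
                raise ValueError(f"locus {locus}: no genotypes in population {pop}")
            hs[pop] = h
        t1, t2 = theta_from_h(hs[pop1]), theta_from_h(hs[pop2])
        results.append(
            LnRHResult(
                locus_id=str(locus), panel=str(panels[0]),
                h_pop1=hs[pop1], h_pop2=hs[pop2],
                theta1=t1, theta2=t2, lnrh=lnrh(hs[pop1], hs[pop2]),
            )
        )
    return standardize(results, z_cutoff=z_cutoff)


@dataclass
class RegionCall:
    region_id: str
    call: str  # "sweep-candidate" | "low-diversity-both" | "no-signal"
    loci: List[LnRHResult]


def sweep_report(
    results: Sequence[LnRHResult],
    region_of: Mapping[str, str],
    low_diversity_quantile: float = 0.05,
) -> List[RegionCall]:
    """Per-region consensus over its candidate microsatellites.

    A region is a sweep-candidate when any of its loci is flagged;
    low-diversity-both when every locus has both populations' H below the
    given quantile of the neutral panel's pooled H values; otherwise
    no-signal. Regions mapping to zero loci are skipped with a warning.
    Inconsistent per-locus flags are preserved verbatim in ``loci``.
    """
    neutral_h = [
        h for r in results if r.panel == "neutral" for h in (r.h_pop1, r.h_pop2)
    ]
    if not neutral_h:
        raise ValueError("no neutral loci available for the diversity quantile")
    h_cut = float(np.quantile(neutral_h, low_diversity_quantile))

    by_region: Dict[str, List[LnRHResult]] = {}
    for r in results:
        region = region_of.get(r.locus_id)
        if region is not None:
            by_region.setdefault(region, []).append(r)

    calls = []
    for region in sorted(set(region_of.values())):
        loci = by_region.get(region, [])
        if not loci:
            logger.warning("region %s has zero mapped loci; skipped", region)
            continue
        if any(r.flagged for r in loci):
            verdict = "sweep-candidate"
        elif all(r.h_pop1 < h_cut and r.h_pop2 < h_cut for r in loci):
            verdict = "low-diversity-both"
        else:
            verdict = "no-signal"
        calls.append(RegionCall(region_id=region, call=verdict, loci=loci))
    return calls
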