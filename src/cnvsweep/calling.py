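"""Per-sample CNV calling from probe-level log2 ratios.

A CNV is a maximal run of at least ``min_probes`` consecutive probes within
one target region whose log2 ratios all exceed ``+tau`` (amplification) or
all fall below ``-tau`` (deletion). Calls sparser than ``max_density`` bp
per probe are removed by :func:`density_filter`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _st

from ._exact import fisher_exact_two_sided

logger = logging.getLogger(__name__)

AMPLIFICATION = "amplification"
DELETION = "deletion"

PROBE_COLUMNS = ["chrom", "start", "end", "region_id", "log2_ratio"]


@dataclass(frozen=True)
class CnvCall:
    """A called amplification or deletion segment in one sample."""

    sample_id: str
    chrom: str
    start: int  # first probe start
    end: int  # last probe end (half-open)
    n_probes: int
    sign: str  # AMPLIFICATION or DELETION
    mean_log2: float

    def __post_init__(self):
        if self.sign not in (AMPLIFICATION, DELETION):
            raise ValueError(f"invalid sign {self.sign!r}")
        if self.end - self.start < 1:
            raise ValueError("call length must be >= 1 bp")
        if self.n_probes < 1:
            raise ValueError("call must contain probes")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        """bp per probe: length / n_probes, exactly."""
        return self.length / self.n_probes


@dataclass(frozen=True)
class CallParams:
    tau: float = 0.5
    min_probes: int = 3
    max_density: float = 2000.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.max_density <= 0:
            raise ValueError("max_density must be > 0")


@dataclass
class ProbeTrack:
    """One sample's ordered probes with log2 ratios."""

    sample_id: str
    population: str
    probes: pd.DataFrame  # columns: chrom, start, end, region_id, log2_ratio

    def __post_init__(self):
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table missing columns {missing}")
        self.probes = self.probes.reset_index(drop=True)

    def validate(self) -> None:
        df = self.probes
        if not np.isfinite(df["log2_ratio"].to_numpy(float)).all():
            raise ValueError("non-finite log2 ratio in track")
        for chrom, g in df.groupby("chrom", sort=False):
            starts = g["start"].to_numpy()
            if len(starts) > 1 and not (np.diff(starts) > 0).all():
                raise ValueError(
                    f"track {self.sample_id}: probes on {chrom} not strictly "
                    "increasing by start (unsorted or duplicated)"
                )


def call_cnvs(track: ProbeTrack, params: CallParams = CallParams()) -> List[CnvCall]:
    """Call CNVs as maximal same-sign threshold runs within each region.

    Runs never cross region boundaries; runs shorter than
    ``params.min_probes`` are discarded. Output is sorted by
    (chromosome, start).
    """
    df = track.probes
    if len(df) == 0:
        return []
    track.validate()

    r = df["log2_ratio"].to_numpy(float)
    sign = np.where(r > params.tau, 1, np.where(r < -params.tau, -1, 0))
    # runs break on sign change or on region/chromosome change
    grp_key = df["chrom"].astype(str) + "\x00" + df["region_id"].astype(str)
    grp = pd.factorize(grp_key)[0]
    brk = np.flatnonzero((sign[1:] != sign[:-1]) | (grp[1:] != grp[:-1])) + 1
    edges = np.concatenate([[0], brk, [len(r)]])

    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()

    calls: List[CnvCall] = []
    for i0, i1 in zip(edges[:-1], edges[1:]):
        s = sign[i0]
        if s == 0 or (i1 - i0) < params.min_probes:
            continue
        calls.append(
            CnvCall(
                sample_id=track.sample_id,
                chrom=str(chroms[i0]),
                start=int(starts[i0]),
                end=int(ends[i1 - 1]),
                n_probes=int(i1 - i0),
                sign=AMPLIFICATION if s > 0 else DELETION,
                mean_log2=float(r[i0:i1].mean()),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def density_filter(calls: Sequence[CnvCall], params: CallParams = CallParams()) -> List[CnvCall]:
    """Retain calls with density <= max_density (inclusive boundary)."""
    kept = [c for c in calls if c.density <= params.max_density]
    removed = len(calls) - len(kept)
    if removed:
        logger.info("density filter removed %d of %d calls", removed, len(calls))
    return kept


@dataclass
class SampleSummary:
    sample_id: Optional[str]
    n_cnvs: int
    n_amplifications: int
    n_deletions: int
    size_median: Optional[float]
    size_mean: Optional[float]
    probes_median: Optional[float]
    probes_mean: Optional[float]
    densities: Tuple[float, ...] = field(default_factory=tuple)

    @property
    def defined(self) -> bool:
        return self.n_cnvs > 0


def summarize_sample(calls: Sequence[CnvCall], sample_id: Optional[str] = None) -> SampleSummary:
    """Summary statistics over one sample's retained calls.

    Medians use the midpoint-of-two convention for even counts. An empty
    call list yields zero counts with the statistics flagged undefined
    (``None``).
    """
    if sample_id is None and calls:
        sample_id = calls[0].sample_id
    if not calls:
        return SampleSummary(sample_id, 0, 0, 0, None, None, None, None, ())
    sizes = np.array([c.length for c in calls], float)
    nprobes = np.array([c.n_probes for c in calls], float)
    return SampleSummary(
        sample_id=sample_id,
        n_cnvs=len(calls),
        n_amplifications=sum(c.sign == AMPLIFICATION for c in calls),
        n_deletions=sum(c.sign == DELETION for c in calls),
        size_median=float(np.median(sizes)),
        size_mean=float(sizes.mean()),
        probes_median=float(np.median(nprobes)),
        probes_mean=float(nprobes.mean()),
        densities=tuple(c.density for c in calls),
    )


def combine_population_counts(counts_by_pop: Mapping[str, Mapping[str, int]]) -> Dict[str, int]:
    """Sum per-population call counts into combined totals.

    Accepts mappings with any of the keys ``n_cnvs``, ``n_amplifications``,
    ``n_deletions`` (missing keys count as 0) and returns the combined
    totals keyed ``total``, ``amplifications``, ``deletions``.
    """
    out = {"total": 0, "amplifications": 0, "deletions": 0}
    for counts in counts_by_pop.values():
        out["total"] += int(counts.get("n_cnvs", 0))
        out["amplifications"] += int(counts.get("n_amplifications", 0))
        out["deletions"] += int(counts.get("n_deletions", 0))
    return out


def compare_populations(
    calls_by_sample: Mapping[str, Sequence[CnvCall]],
    pop_of: Mapping[str, str],
) -> Dict[str, object]:
    """Between-population comparison report.

    Computes (a) two-sample Kolmogorov-Smirnov tests (asymptotic p) on CNV
    size, probes-per-CNV and density distributions; (b) a two-sided
    Mann-Whitney U test (normal approximation with tie correction) on
    per-sample CNV counts; (c) a two-sided Fisher exact test on the 2x2
    amplification/deletion x population table; and (d) a Mann-Whitney U
    test of per-sample deletion counts against per-sample amplification
    counts pooled over both populations.
    """
    pops = sorted(set(pop_of.values()))
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    samples_by_pop = {p: [s for s in calls_by_sample if pop_of[s] == p] for p in pops}
    for p, ss in samples_by_pop.items():
        if not ss:
            raise ValueError(f"population {p!r} has zero samples")

    pooled = {p: [c for s in samples_by_pop[p] for c in calls_by_sample[s]] for p in pops}
    report: Dict[str, object] = {"populations": tuple(pops)}

    def _ks(attr):
        x = np.array([getattr(c, attr) for c in pooled[pops[0]]], float)
        y = np.array([getattr(c, attr) for c in pooled[pops[1]]], float)
        if len(x) == 0 or len(y) == 0:
            return {"D": None, "p": None}
        res = _st.ks_2samp(x, y, method="asymp")
        return {"D": float(res.statistic), "p": float(res.pvalue)}

    report["ks_size"] = _ks("length")
    report["ks_probes"] = _ks("n_probes")
    report["ks_density"] = _ks("density")

    counts = {p: [len(calls_by_sample[s]) for s in samples_by_pop[p]] for p in pops}
    mwu = _st.mannwhitneyu(counts[pops[0]], counts[pops[1]], alternative="two-sided", method="asymptotic")
    report["mwu_counts"] = {"U": float(mwu.statistic), "p": float(mwu.pvalue)}

    amp = {p: sum(c.sign == AMPLIFICATION for c in pooled[p]) for p in pops}
    dele = {p: sum(c.sign == DELETION for c in pooled[p]) for p in pops}
    table = [[amp[pops[0]], amp[pops[1]]], [dele[pops[0]], dele[pops[1]]]]
    odds, p_fisher = fisher_exact_two_sided(table)
    report["fisher_amp_del"] = {"table": table, "odds_ratio": odds, "p": p_fisher}

    all_samples = list(calls_by_sample)
    del_counts = [sum(c.sign == DELETION for c in calls_by_sample[s]) for s in all_samples]
    amp_counts = [sum(c.sign == AMPLIFICATION for c in calls_by_sample[s]) for s in all_samples]
    mwu2 = _st.mannwhitneyu(del_counts, amp_counts, alternative="two-sided", method="asymptotic")
    report["mwu_del_vs_amp"] = {"U": float(mwu2.statistic), "p": float(mwu2.pvalue)}
    return report
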