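"""Synthetic inputs with known truth sets.

Generators for: probe layouts tiling flank-extended gene regions, CGH
probe tracks with injected amplifications/deletions, diploid microsatellite
genotypes with optional sweep signatures, per-gene expression statistics
optionally coupled to CNV state, and gene feature models. Every generator
is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _st

from .calling import ProbeTrack
from .overlap import Feature

PROBE_LENGTH = 60  # bp, fixed oligo length


class Region(NamedTuple):
    chrom: str
    start: int
    end: int
    gene_id: str


@dataclass
class RegionSet:
    """Target gene regions, each extended by ``flank`` bp on both sides."""

    regions: List[Region]
    flank: int = 10000

    def __post_init__(self):
        self.regions = sorted((Region(*r) for r in self.regions), key=lambda r: (r.chrom, r.start))
        for r in self.regions:
            if r.start >= r.end:
                raise ValueError(f"region {r.gene_id}: start >= end")
            if r.start < 0:
                raise ValueError(f"region {r.gene_id}: negative coordinate")
        prev = None
        for r in self.flanked():
            if prev is not None and r.chrom == prev.chrom and r.start < prev.end:
                raise ValueError(
                    f"regions {prev.gene_id} and {r.gene_id} overlap after flank "
                    "extension; merge them first"
                )
            prev = r

    def flanked(self) -> List[Region]:
        return [
            Region(r.chrom, max(0, r.start - self.flank), r.end + self.flank, r.gene_id)
            for r in self.regions
        ]


@dataclass
class ProbeLayout:
    probes: pd.DataFrame  # columns: chrom, start, end, region_id
    spacing: int = 170


def generate_probe_layout(regions: RegionSet, spacing: int = 170) -> ProbeLayout:
    """Tile each flank-extended region with left-anchored probes.

    Probes are placed every ``spacing`` bp from the region start; each
    region gets floor(length / spacing) probes, minimum one. Probe ends
    are clipped to the region end.
    """
    if not regions.regions:
        raise ValueError("empty region set")
    if spacing < PROBE_LENGTH:
        raise ValueError(f"spacing must be >= probe length ({PROBE_LENGTH} bp)")
    rows = []
    for r in regions.flanked():
        length = r.end - r.start
        n = max(1, length // spacing)
        for i in range(n):
            s = r.start + i * spacing
            rows.append((r.chrom, s, min(s + PROBE_LENGTH, r.end), r.gene_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return ProbeLayout(probes=df, spacing=spacing)


def _shift_for_copy_state(copy_state: int, zero_floor: float) -> float:
    if copy_state < 0 or copy_state == 2:
        raise ValueError(f"copy_state must be >= 0 and != 2, got {copy_state}")
    return zero_floor if copy_state == 0 else math.log2(copy_state / 2)


@dataclass(frozen=True)
class TruthCnv:
    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: int
    expected_shift: float = field(default=None)  # type: ignore[assignment]
    zero_floor: float = -3.0

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("truth CNV must span >= 1 bp")
        shift = _shift_for_copy_state(self.copy_state, self.zero_floor)
        if self.expected_shift is None:
            object.__setattr__(self, "expected_shift", shift)
        elif not math.isclose(self.expected_shift, shift):
            raise ValueError("expected_shift inconsistent with copy_state")


@dataclass
class SimConfig:
    n_samples_per_pop: int = 5
    noise_sd: float = 0.15
    batch_sd_inflation: float = 1.0
    batch_samples: Tuple[int, ...] = ()  # indices into the full sample list
    cnv_size_range: Tuple[int, int] = (200, 600_000)
    pop_frequencies: Tuple[Tuple[float, float], ...] = ()  # per locus, per population
    copy_states: Optional[Tuple[int, ...]] = None  # per locus; random if None
    zero_floor_shift: float = -3.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_samples_per_pop < 1:
            raise ValueError("n_samples_per_pop must be >= 1")
        lo, hi = self.cnv_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid cnv_size_range")
        for fp in self.pop_frequencies:
            for f in fp:
                if not 0 <= f <= 1:
                    raise ValueError("carrier frequencies must lie in [0, 1]")
        if self.copy_states is not None and len(self.copy_states) != len(self.pop_frequencies):
            raise ValueError("copy_states must match pop_frequencies in length")


def simulate_cgh(
    layout: ProbeLayout,
    config: SimConfig,
    populations: Tuple[str, str] = ("pop1", "pop2"),
    events: Optional[Sequence[TruthCnv]] = None,
) -> Tuple[List[ProbeTrack], List[TruthCnv]]:
    """Simulate per-sample probe tracks with a recorded truth set.

    Each probe's log2 ratio is the expected shift of any overlapping truth
    CNV for that sample (0 elsewhere) plus Gaussian noise of sd
    ``noise_sd``, inflated by ``batch_sd_inflation`` for samples listed in
    ``batch_samples``. When ``events`` is given, those exact truth CNVs are
    injected (validated against the layout span) instead of drawing random
    loci from ``pop_frequencies``.
    """
    probes = layout.probes
    if len(probes) == 0:
        raise ValueError("layout has no probes")
    rng = np.random.default_rng(config.seed)
    sample_ids = [
        f"{pop}_s{i + 1}" for pop in populations for i in range(config.n_samples_per_pop)
    ]
    pop_of = {
        sid: populations[0] if j < config.n_samples_per_pop else populations[1]
        for j, sid in enumerate(sample_ids)
    }

    span_by_chrom = {
        chrom: (int(g["start"].min()), int(g["end"].max()))
        for chrom, g in probes.groupby("chrom")
    }

    if events is not None:
        truths = list(events)
        for t in truths:
            span = span_by_chrom.get(t.chrom)
            if span is None or t.end <= span[0] or t.start >= span[1]:
                raise ValueError(f"injected CNV {t} lies outside the probe layout span")
            if t.sample_id not in pop_of:
                raise ValueError(f"injected CNV sample {t.sample_id!r} not simulated")
    else:
        truths = _draw_truths(probes, config, rng, sample_ids, pop_of, populations)

    truth_by_sample: Dict[str, List[TruthCnv]] = {sid: [] for sid in sample_ids}
    for t in truths:
        truth_by_sample[t.sample_id].append(t)

    p_start = probes["start"].to_numpy()
    p_end = probes["end"].to_numpy()
    p_chrom = probes["chrom"].to_numpy()

    tracks = []
    for j, sid in enumerate(sample_ids):
        base = np.zeros(len(probes))
        for t in truth_by_sample[sid]:
            mask = (p_chrom == t.chrom) & (p_start < t.end) & (p_end > t.start)
            base[mask] = t.expected_shift
        sd = config.noise_sd * (config.batch_sd_inflation if j in config.batch_samples else 1.0)
        values = base + rng.normal(0.0, sd, size=len(probes))
        df = probes.copy()
        df["log2_ratio"] = values
        tracks.append(ProbeTrack(sample_id=sid, population=pop_of[sid], probes=df))
    return tracks, truths


def _draw_truths(probes, config, rng, sample_ids, pop_of, populations):
    region_spans = [
        (chrom, int(g["start"].min()), int(g["end"].max()))
        for (chrom, _), g in probes.groupby(["chrom", "region_id"], sort=True)
    ]
    lo, hi = config.cnv_size_range
    truths = []
    for i, freqs in enumerate(config.pop_frequencies):
        chrom, r_start, r_end = region_spans[int(rng.integers(0, len(region_spans)))]
        span_len = r_end - r_start
        size = int(rng.integers(lo, min(hi, span_len) + 1)) if span_len > lo else span_len
        offset = int(rng.integers(0, span_len - size + 1)) if span_len > size else 0
        start, end = r_start + offset, r_start + offset + size
        if config.copy_states is not None:
            copy_state = config.copy_states[i]
        else:
            copy_state = int(rng.choice([0, 1, 3, 4]))
        for sid in sample_ids:
            freq = freqs[populations.index(pop_of[sid])]
            if rng.random() < freq:
                truths.append(
                    TruthCnv(sid, chrom, start, end, copy_state, zero_floor=config.zero_floor_shift)
                )
    return truths


@dataclass
class MicrosatSimConfig:
    n_individuals_per_pop: int = 46
    n_neutral: int = 64
    n_candidate: int = 6
    ancestral_n_alleles: int = 8
    motif: int = 2  # 2 or 3 bp
    base_length: Optional[int] = None  # fixed ladder base; random per locus if None
    sweep_factor: float = 1.0  # (0, 1]; 1 = neutral
    swept_candidates: Tuple[int, ...] = ()  # candidate indices carrying the sweep
    swept_population_index: int = 1  # which population the sweep acts in
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals_per_pop < 2:
            raise ValueError("need >= 2 individuals per population for the H estimator")
        if not 0 < self.sweep_factor <= 1:
            raise ValueError("sweep_factor must lie in (0, 1]")
        if self.motif not in (2, 3):
            raise ValueError("motif must be 2 or 3 bp")
        if self.ancestral_n_alleles < 2:
            raise ValueError("need >= 2 ancestral alleles")
        for i in self.swept_candidates:
            if not 0 <= i < self.n_candidate:
                raise ValueError(f"swept candidate index {i} out of range")


def simulate_microsats(
    config: MicrosatSimConfig,
    populations: Tuple[str, str] = ("pop1", "pop2"),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate diploid microsatellite genotypes for two populations.

    Neutral loci (and unswept candidates) draw both populations' genotypes
    from one shared ancestral allele-frequency vector (Dirichlet(1,...,1)).
    A swept candidate's target-population frequencies are concentrated by
    tempering: q_i proportional to p_i^(1/sweep_factor), which leaves the
    vector unchanged at sweep_factor = 1 and approaches fixation of the
    major allele as sweep_factor -> 0.

    Returns ``(genotypes, truth)``: a long table (locus, population,
    individual, allele1_bp, allele2_bp, panel) and the per-locus truth
    (locus, panel, swept).
    """
    rng = np.random.default_rng(config.seed)
    n_alleles = config.ancestral_n_alleles
    rows = []
    truth_rows = []
    loci = [(f"neutral_{i + 1:03d}", "neutral", False) for i in range(config.n_neutral)] + [
        (f"candidate_{i + 1:03d}", "candidate", i in config.swept_candidates)
        for i in range(config.n_candidate)
    ]
    for locus_id, panel, swept in loci:
        if config.base_length is not None:
            base = config.base_length
        else:
            base = 100 + config.motif * int(rng.integers(5, 16))
        lengths = base + config.motif * np.arange(n_alleles)
        p = rng.dirichlet(np.ones(n_alleles))
        for pi, pop in enumerate(populations):
            freqs = p
            if swept and pi == config.swept_population_index and config.sweep_factor < 1:
                q = p ** (1.0 / config.sweep_factor)
                freqs = q / q.sum()
            draws = rng.choice(n_alleles, size=(config.n_individuals_per_pop, 2), p=freqs)
            for ind in range(config.n_individuals_per_pop):
                rows.append(
                    (
                        locus_id,
                        pop,
                        f"{pop}_i{ind + 1}",
                        int(lengths[draws[ind, 0]]),
                        int(lengths[draws[ind, 1]]),
                        panel,
                    )
                )
        truth_rows.append((locus_id, panel, swept))
    genotypes = pd.DataFrame(
        rows, columns=["locus", "population", "individual", "allele1_bp", "allele2_bp", "panel"]
    )
    truth = pd.DataFrame(truth_rows, columns=["locus", "panel", "swept"])
    return genotypes, truth


@dataclass
class ExprSimConfig:
    tissues: Tuple[str, ...] = ("brain", "liver", "testis")
    platforms: Tuple[str, ...] = ("A", "B")
    de_fraction: float = 0.1  # background chance a non-coupled gene is DE
    effect: float = 4.0  # noncentrality of shifted t statistics
    df: int = 10
    sign_match_prob: float = 1.0  # chance a coupled shift matches the copy change
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0 <= self.sign_match_prob <= 1:
            raise ValueError("sign_match_prob must lie in [0, 1]")


def simulate_expression_stats(
    genes: pd.DataFrame,
    coupling: float,
    config: ExprSimConfig = ExprSimConfig(),
) -> pd.DataFrame:
    """Simulate per-gene expression statistics across tissues and platforms.

    ``genes`` needs columns gene_id, cnv_sign (+1 amplification, -1
    deletion, 0 none). With probability ``coupling`` a CNV-carrying gene
    receives a true expression shift whose sign matches its copy change
    with probability ``sign_match_prob``; other genes are DE with the
    background ``de_fraction`` and a random sign. Null genes draw central
    t statistics, so their p-values are uniform.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    if "gene_id" not in genes.columns or "cnv_sign" not in genes.columns:
        raise ValueError("genes table needs gene_id and cnv_sign columns")
    rng = np.random.default_rng(config.seed)
    rows = []
    for _, gene in genes.iterrows():
        sign = int(gene["cnv_sign"])
        if sign != 0 and rng.random() < coupling:
            shift = sign if rng.random() < config.sign_match_prob else -sign
        elif rng.random() < config.de_fraction:
            shift = int(rng.choice([-1, 1]))
        else:
            shift = 0
        status = "DE" if shift else "invariant"
        for tissue in config.tissues:
            for platform in config.platforms:
                t = float(rng.standard_t(config.df)) + shift * config.effect
                p = float(2 * _st.t.sf(abs(t), config.df))
                rows.append((gene["gene_id"], tissue, platform, p, t, status))
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "platform", "p_value", "t_statistic", "status"]
    )


def make_gene_models(
    regions: RegionSet,
    exons_per_gene: int = 3,
    exon_length: int = 200,
    utr_exon_length: Optional[int] = None,
) -> List[Feature]:
    """Partition each gene body into 5'-exon, introns, internal exons, 3'-exon.

    The 5'-exon opens the gene and the 3'-exon closes it (both of
    ``utr_exon_length``, default ``exon_length``); ``exons_per_gene``
    internal exons of ``exon_length`` are spread through the interior with
    introns filling every gap. Features tile the gene interval exactly.
    """
    if exons_per_gene < 0:
        raise ValueError("exons_per_gene must be >= 0")
    ul = exon_length if utr_exon_length is None else utr_exon_length
    features: List[Feature] = []
    for r in regions.regions:
        gene_len = r.end - r.start
        k = exons_per_gene
        exon_total = 2 * ul + k * exon_length
        n_introns = k + 1
        if exon_total + n_introns > gene_len:
            raise ValueError(
                f"gene {r.gene_id}: exon lengths ({exon_total} bp + {n_introns} introns) "
                f"exceed gene length {gene_len} bp"
            )
        intron_total = gene_len - exon_total
        base, rem = divmod(intron_total, n_introns)
        intron_lens = [base + (1 if i < rem else 0) for i in range(n_introns)]
        pos = r.start
        features.append(Feature(r.chrom, pos, pos + ul, r.gene_id, "exon5"))
        pos += ul
        for i in range(k):
            features.append(Feature(r.chrom, pos, pos + intron_lens[i], r.gene_id, "intron"))
            pos += intron_lens[i]
            features.append(Feature(r.chrom, pos, pos + exon_length, r.gene_id, "exon"))
            pos += exon_length
        features.append(Feature(r.chrom, pos, pos + intron_lens[k], r.gene_id, "intron"))
        pos += intron_lens[k]
        features.append(Feature(r.chrom, pos, pos + ul, r.gene_id, "exon3"))
        assert pos + ul == r.end
    return features


def random_regions(
    n: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
    gene_length: Tuple[int, int] = (5000, 20000),
    flank: int = 10000,
    gap: Optional[int] = None,
) -> RegionSet:
    """Convenience: n non-overlapping genes on one chromosome."""
    if gap is None:
        gap = 2 * flank + 1000
    regions = []
    pos = 1000
    for i in range(n):
        length = int(rng.integers(gene_length[0], gene_length[1] + 1))
        regions.append(Region(chrom, pos, pos + length, f"gene_{i + 1:04d}"))
        pos += length + gap
    return RegionSet(regions=regions, flank=flank)
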