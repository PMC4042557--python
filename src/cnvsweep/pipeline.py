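"""End-to-end pipeline driver with reproducible per-stage seeding.

Stage seeds are derived as ``numpy.random.SeedSequence([seed, stage_index])
.generate_state(1)[0]`` so each stage has an independent, documented
stream and re-running with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as cio
from . import __version__
from .calling import CallParams, call_cnvs, combine_population_counts, compare_populations, density_filter, summarize_sample
from .differentiation import cluster_calls, flag_differentiating
from .expression import classify_locus, direction_concordance
from .overlap import CnvInterval, intersect, summarize_overlaps
from .sweep import scan, sweep_report
from .synthetic import (
    ExprSimConfig,
    MicrosatSimConfig,
    SimConfig,
    generate_probe_layout,
    make_gene_models,
    random_regions,
    simulate_cgh,
    simulate_expression_stats,
    simulate_microsats,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call-cnvs", "diff-loci", "overlap", "expr-assoc", "sweep-scan")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "cnvsweep_out"
    seed: int = 0
    # input paths; filled by the simulate stage when simulate=True
    probes: Optional[str] = None
    features: Optional[str] = None
    expression: Optional[str] = None
    genotypes: Optional[str] = None
    simulate: bool = True
    n_regions: int = 20
    call_params: CallParams = field(default_factory=CallParams)
    alpha: float = 0.05
    min_major: int = 4
    max_minor: int = 1
    min_frac_of_cnv: float = 0.10
    numerator_population: str = "pop1"
    run_sweep: bool = True
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = cio.load_yaml(path)
        call = data.pop("call_params", {})
        cfg = cls(**data)
        if call:
            cfg.call_params = CallParams(**call)
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    version: str
    config: dict
    outputs: Dict[str, str]  # file name -> sha256
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _stage_seed(seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run simulate (optional) -> call-cnvs -> diff-loci -> overlap ->
    expr-assoc -> sweep-scan, writing each stage's outputs to ``out_dir``.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs written before the failure are retained.
    """
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}

    def _emit(name: str):
        outputs[name] = _sha256(out / name)

    probes_path = config.probes
    features_path = config.features
    expression_path = config.expression
    genotypes_path = config.genotypes

    # --- simulate -----------------------------------------------------------
    if config.simulate:
        try:
            rng = np.random.default_rng(_stage_seed(config.seed, 0))
            regions = random_regions(config.n_regions, rng, flank=2000, gene_length=(4000, 8000))
            layout = generate_probe_layout(regions)
            n_loci = max(4, config.n_regions // 2)
            freqs = []
            for i in range(n_loci):
                f1 = float(rng.choice([0.1, 0.5, 0.9]))
                f2 = float(rng.choice([0.1, 0.5, 0.9]))
                freqs.append((f1, f2))
            sim = SimConfig(pop_frequencies=tuple(freqs), seed=_stage_seed(config.seed, 1))
            tracks, truths = simulate_cgh(layout, sim)
            features = make_gene_models(regions, exons_per_gene=2, exon_length=150)

            probes_path = str(out / "probes.tsv")
            cio.write_probe_tracks(tracks, probes_path)
            features_path = str(out / "features.bed")
            cio.write_features_bed(features, features_path)
            cio.write_bed(
                (
                    cio.BedRecord(t.chrom, t.start, t.end, f"{t.sample_id}:{t.copy_state}")
                    for t in truths
                ),
                out / "truth.bed",
            )

            gene_table = _gene_table_from_truth(regions, truths)
            stats = simulate_expression_stats(
                gene_table, coupling=0.5, config=ExprSimConfig(seed=_stage_seed(config.seed, 2))
            )
            expression_path = str(out / "expression.tsv")
            cio.write_expression(stats, expression_path)

            ms_cfg = MicrosatSimConfig(
                n_candidate=4, sweep_factor=0.05, swept_candidates=(0,),
                seed=_stage_seed(config.seed, 3),
            )
            genotypes, ms_truth = simulate_microsats(ms_cfg)
            genotypes_path = str(out / "genotypes.csv")
            cio.write_genotypes(genotypes, genotypes_path)
            ms_truth.to_csv(out / "genotypes_truth.csv", index=False)

            for name in ("probes.tsv", "features.bed", "truth.bed", "expression.tsv",
                         "genotypes.csv", "genotypes_truth.csv"):
                _emit(name)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", exc) from exc

    # --- call-cnvs ----------------------------------------------------------
    try:
        if probes_path is None:
            raise FileNotFoundError("no probe track file configured")
        tracks = cio.read_probe_tracks(probes_path)
        calls_by_sample = {}
        pop_of = {}
        for t in tracks:
            calls = density_filter(call_cnvs(t, config.call_params), config.call_params)
            calls_by_sample[t.sample_id] = calls
            pop_of[t.sample_id] = t.population
        all_calls = [c for cs in calls_by_sample.values() for c in cs]
        cio.write_calls_tsv(all_calls, out / "calls.tsv")
        cio.write_calls_bed(all_calls, out / "calls.bed")
        summaries = [summarize_sample(cs, sid) for sid, cs in calls_by_sample.items()]
        cio.write_summaries(summaries, out / "sample_summaries.tsv")

        pops = sorted(set(pop_of.values()))
        counts_by_pop = {
            p: {
                "n_cnvs": sum(s.n_cnvs for s in summaries if pop_of[s.sample_id] == p),
                "n_amplifications": sum(
                    s.n_amplifications for s in summaries if pop_of[s.sample_id] == p
                ),
                "n_deletions": sum(s.n_deletions for s in summaries if pop_of[s.sample_id] == p),
            }
            for p in pops
        }
        report = {"combined": combine_population_counts(counts_by_pop)}
        for p in pops:
            report[p] = counts_by_pop[p]
        if len(pops) == 2 and all(any(pop_of[s] == p for s in calls_by_sample) for p in pops):
            report["comparison"] = compare_populations(calls_by_sample, pop_of)
        cio.write_key_value_report(report, out / "population_report.tsv")
        for name in ("calls.tsv", "calls.bed", "sample_summaries.tsv", "population_report.tsv"):
            _emit(name)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("call-cnvs", exc) from exc

    # --- diff-loci ----------------------------------------------------------
    try:
        loci = cluster_calls(all_calls, pop_of)
        results = flag_differentiating(
            loci, alpha=config.alpha, min_major=config.min_major, max_minor=config.max_minor
        )
        cio.write_loci(loci, results, out / "loci.tsv")
        _emit("loci.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("diff-loci", exc) from exc

    # --- overlap ------------------------------------------------------------
    try:
        if features_path is None:
            raise FileNotFoundError("no feature file configured")
        features = cio.read_features_bed(features_path)
        intervals = [
            CnvInterval(f"{c.sample_id}:{c.chrom}:{c.start}-{c.end}", c.chrom, c.start, c.end)
            for c in all_calls
        ]
        records = intersect(intervals, features, config.min_frac_of_cnv)
        cio.write_overlap_records(records, out / "overlaps.tsv")
        summary = summarize_overlaps(records)
        cio.write_key_value_report(
            {
                "element_counts": summary.element_counts,
                "shares": summary.shares,
                "n_genes": summary.n_genes,
            },
            out / "overlap_summary.tsv",
        )
        _emit("overlaps.tsv")
        _emit("overlap_summary.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("overlap", exc) from exc

    # --- expr-assoc ---------------------------------------------------------
    try:
        if expression_path is None:
            raise FileNotFoundError("no expression statistics file configured")
        stats = cio.read_expression(expression_path)
        feature_by_gene: Dict[str, List] = {}
        for f in features:
            feature_by_gene.setdefault(f.gene_id, []).append(f)
        flagged_ids = {r.locus_id for r in results if r.is_differentiating}
        conc_records = []
        for locus in loci:
            if locus.locus_id not in flagged_ids:
                continue
            genes = {
                f.gene_id
                for f in features
                if f.chrom == locus.chrom
                and f.start < locus.footprint_end
                and f.end > locus.footprint_start
            }
            conc_records.append(
                classify_locus(locus.locus_id, locus.sign, stats[stats["gene_id"].isin(genes)])
            )
        report = direction_concordance(conc_records) if conc_records else None
        payload = {"n_differentiating": len(flagged_ids)}
        if report is not None:
            payload.update({"counts": report.counts, "total": report.total,
                            "p_binomial": report.p_binomial})
        cio.write_key_value_report(payload, out / "expression_association.tsv")
        _emit("expression_association.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expr-assoc", exc) from exc

    # --- sweep-scan ---------------------------------------------------------
    if config.run_sweep:
        try:
            if genotypes_path is None:
                raise FileNotFoundError("no genotype file configured")
            genotypes = cio.read_genotypes(genotypes_path)
            results_ln = scan(genotypes, config.numerator_population)
            cio.write_lnrh_results(results_ln, out / "lnrh.tsv")
            candidates = [r for r in results_ln if r.panel == "candidate"]
            region_of = {r.locus_id: r.locus_id.rsplit("_", 1)[0] + "_region_" + r.locus_id.rsplit("_", 1)[1]
                         for r in candidates}
            regions_report = sweep_report(results_ln, region_of)
            cio.write_region_report(regions_report, out / "sweep_regions.tsv")
            _emit("lnrh.tsv")
            _emit("sweep_regions.tsv")
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("sweep-scan", exc) from exc

    manifest = RunManifest(
        version=__version__,
        config=config.snapshot(),
        outputs=outputs,
        started=started,
        finished=time.time(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _gene_table_from_truth(regions, truths):
    import pandas as pd

    sign_by_gene: Dict[str, int] = {}
    size_by_gene: Dict[str, int] = {}
    for t in truths:
        for r in regions.regions:
            if r.chrom == t.chrom and t.start < r.end and t.end > r.start:
                sign_by_gene[r.gene_id] = 1 if t.copy_state > 2 else -1
                size_by_gene[r.gene_id] = max(size_by_gene.get(r.gene_id, 0), t.end - t.start)
    rows = [
        {
            "gene_id": r.gene_id,
            "cnv_sign": sign_by_gene.get(r.gene_id, 0),
            "cnv_size": size_by_gene.get(r.gene_id, 0),
        }
        for r in regions.regions
    ]
    return pd.DataFrame(rows)
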