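"""Readers and writers for the plain-text formats used by the pipeline.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based,
fully closed) is converted at the reader boundary. TSV outputs carry a
one-line header and no comment metadata.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .calling import AMPLIFICATION, CnvCall, ProbeTrack, SampleSummary
from .differentiation import CnvLocus, DifferentiationResult
from .overlap import Feature, OverlapRecord
from .sweep import LnRHResult, RegionCall

logger = logging.getLogger(__name__)

_GFF_CLASS_MAP = {
    "intron": "intron",
    "exon": "exon",
    "three_prime_UTR": "exon3",
    "five_prime_UTR": "exon5",
}


class BedRecord(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "."


class FormatError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


def read_bed(path) -> List[BedRecord]:
    """Read BED (>= 3 columns, 0-based half-open) into records."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            records.append(BedRecord(parts[0], start, end, name, score, strand))
    return records


def write_bed(records: Iterable[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


def write_features_bed(features: Sequence[Feature], path) -> None:
    """Features as BED with ``gene_id|class`` in the name column."""
    write_bed(
        (BedRecord(f.chrom, f.start, f.end, f"{f.gene_id}|{f.feature_class}") for f in features),
        path,
    )


def read_features_bed(path) -> List[Feature]:
    features = []
    for r in read_bed(path):
        if "|" not in r.name:
            raise FormatError(f"{path}: feature name {r.name!r} lacks 'gene|class' form")
        gene_id, cls = r.name.rsplit("|", 1)
        features.append(Feature(r.chrom, r.start, r.end, gene_id, cls))
    return features


def read_gff3_features(path) -> Tuple[List[Feature], int]:
    """Read mappable features from GFF3, converting to 0-based half-open.

    Types intron / exon / three_prime_UTR / five_prime_UTR are kept; other
    types are skipped and counted. Returns ``(features, n_skipped)``.
    """
    features = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 GFF3 columns")
            ftype = parts[2]
            if ftype not in _GFF_CLASS_MAP:
                skipped += 1
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene_id = _gff_gene_id(parts[8])
            features.append(
                Feature(parts[0], start1 - 1, end1, gene_id, _GFF_CLASS_MAP[ftype])
            )
    if skipped:
        logger.info("read_gff3_features: skipped %d unmappable feature lines", skipped)
    return features, skipped


def _gff_gene_id(attributes: str) -> str:
    attrs = {}
    for item in attributes.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID") or "."


# --- probe tracks -----------------------------------------------------------

TRACK_COLUMNS = ["sample_id", "population", "chrom", "start", "end", "region_id", "log2_ratio"]


def write_probe_tracks(tracks: Sequence[ProbeTrack], path) -> None:
    frames = []
    for t in tracks:
        df = t.probes.copy()
        df.insert(0, "sample_id", t.sample_id)
        df.insert(1, "population", t.population)
        frames.append(df[TRACK_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_probe_tracks(path) -> List[ProbeTrack]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "population", "chrom", "start", "end", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "region_id" not in df.columns:
        df["region_id"] = df["chrom"]
    tracks = []
    for (sid, pop), g in df.groupby(["sample_id", "population"], sort=True):
        probes = g[["chrom", "start", "end", "region_id", "log2_ratio"]].reset_index(drop=True)
        tracks.append(ProbeTrack(sample_id=str(sid), population=str(pop), probes=probes))
    return tracks


# --- calls and summaries ----------------------------------------------------


def write_calls_bed(calls: Sequence[CnvCall], path) -> None:
    """BED6-compatible: name = sample:sign, score = n_probes."""
    write_bed(
        (
            BedRecord(c.chrom, c.start, c.end, f"{c.sample_id}:{c.sign}", str(c.n_probes))
            for c in calls
        ),
        path,
    )


def write_calls_tsv(calls: Sequence[CnvCall], path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "n_probes": c.n_probes,
            "sign": c.sign,
            "mean_log2": c.mean_log2,
            "length": c.length,
            "density": c.density,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "start", "end", "n_probes", "sign", "mean_log2", "length", "density",
    ]).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> List[CnvCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CnvCall(
            sample_id=str(r.sample_id), chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n_probes=int(r.n_probes), sign=str(r.sign), mean_log2=float(r.mean_log2),
        )
        for r in df.itertuples()
    ]


def write_summaries(summaries: Sequence[SampleSummary], path) -> None:
    rows = []
    for s in summaries:
        d = asdict(s)
        d["densities"] = ",".join(f"{x:g}" for x in d.pop("densities"))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_key_value_report(report: Dict[str, object], path) -> None:
    """Flatten a nested report dict into two-column TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in _flatten(report):
            fh.write(f"{key}\t{value}\n")


def _flatten(d, prefix=""):
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, prefix=f"{key}.")
        else:
            yield key, v


def write_loci(
    loci: Sequence[CnvLocus], results: Sequence[DifferentiationResult], path
) -> None:
    by_id = {r.locus_id: r for r in results}
    rows = []
    for l in loci:
        r = by_id[l.locus_id]
        rows.append(
            {
                "chrom": l.chrom,
                "start": l.footprint_start,
                "end": l.footprint_end,
                "locus_id": l.locus_id,
                "sign": l.sign,
                f"k_{l.populations[0]}": l.carriers[0],
                f"k_{l.populations[1]}": l.carriers[1],
                "p_hypergeom": r.p_hypergeom,
                "p_bh": r.p_bh,
                "flagged": r.is_differentiating,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_overlap_records(records: Sequence[OverlapRecord], path) -> None:
    rows = [
        {
            "cnv_id": r.cnv_id,
            "chrom": r.feature.chrom,
            "feature_start": r.feature.start,
            "feature_end": r.feature.end,
            "gene_id": r.feature.gene_id,
            "feature_class": r.feature.feature_class,
            "overlap_bp": r.overlap_bp,
            "fraction_of_cnv": r.fraction_of_cnv,
            "fraction_of_feature": r.fraction_of_feature,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=[
        "cnv_id", "chrom", "feature_start", "feature_end", "gene_id", "feature_class",
        "overlap_bp", "fraction_of_cnv", "fraction_of_feature",
    ]).to_csv(path, sep="\t", index=False)


# --- genotypes and expression ----------------------------------------------


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index=False)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"locus", "population", "individual", "allele1_bp", "allele2_bp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "panel" not in df.columns:
        df["panel"] = "candidate"
    return df


def write_expression(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "tissue", "platform", "p_value", "t_statistic", "status"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_lnrh_results(results: Sequence[LnRHResult], path) -> None:
    rows = [
        {
            "locus": r.locus_id,
            "panel": r.panel,
            "H_pop1": r.h_pop1,
            "H_pop2": r.h_pop2,
            "theta1": r.theta1,
            "theta2": r.theta2,
            "lnRH": r.lnrh,
            "z": r.z,
            "flagged": r.flagged,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_region_report(calls: Sequence[RegionCall], path) -> None:
    rows = [
        {
            "region_id": c.region_id,
            "call": c.call,
            "loci": ",".join(r.locus_id for r in c.loci),
            "z_values": ",".join("" if r.z is None else f"{r.z:.4f}" for r in c.loci),
            "flags": ",".join(str(r.flagged) for r in c.loci),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
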