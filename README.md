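# cnvsweep

CNV discovery and selective-sweep analysis for two-population CGH studies:

- **Run-based CNV calling** from probe-level log2 ratios: maximal runs of
  ≥ 3 consecutive same-sign probes beyond |log2| > 0.5 within one target
  region, followed by a probe-density filter (≤ 2000 bp/probe).
- **Population differentiation**: single-linkage clustering of same-sign
  overlapping calls into loci; a locus differentiates the populations when
  ≥ 4 carriers in one population meet ≤ 1 in the other with a one-tailed
  hypergeometric p < 0.05 (exact integer arithmetic).
- **Genic feature overlap**: CNV × intron/exon/3'-exon/5'-exon intersection
  under the ≥ 10%-of-CNV-length rule, with element counts, class shares and
  median overlap fractions.
- **Expression association**: Spearman CNV-size correlations, exact
  two-sided Fisher DE-vs-invariant enrichment, and exact binomial direction
  concordance for differentiating loci.
- **lnRH sweep scan**: unbiased expected heterozygosity with monomorphic
  correction, stepwise-mutation-model theta, lnRH standardized against a
  neutral microsatellite panel, |z| > 2 flags, and per-region consensus
  calls (sweep-candidate / low-diversity-both / no-signal).
- **Synthetic data**: probe layouts, CGH tracks with truth sets, diploid
  microsatellite genotypes with tunable sweep strength, expression
  statistics with tunable CNV coupling, and gene feature models — all
  seed-deterministic.

## CLI

```bash
cnvsweep simulate   --seed 1 --n-regions 20 --out data/
cnvsweep call-cnvs  --probes data/probes.tsv --out calls.tsv
cnvsweep diff-loci  --probes data/probes.tsv --paper-mode --out loci.tsv
cnvsweep overlap    --calls calls.tsv --features data/features.bed --out overlaps.tsv
cnvsweep expr-assoc --expression expr.tsv --cnv-de 248 --n-de 1861 --cnv-inv 60 --n-inv 506
cnvsweep sweep-scan --genotypes data/genotypes.csv --numerator pop1 --out lnrh.tsv
cnvsweep run-all    --seed 1 --out run/        # full pipeline + manifest.json
```

`diff-loci --paper-mode` pins tau 0.5, min probes 3, max density 2000,
min-major 4, max-minor 1, alpha 0.05. `run-all` accepts a YAML config
(`--config`) mirroring `cnvsweep.pipeline.PipelineConfig` fields; per-stage
seeds are derived from the single config seed via
`numpy.random.SeedSequence([seed, stage_index])`.

All interval files are 0-based half-open (BED convention); GFF3 input is
converted at the reader boundary.

## Layout

```
src/cnvsweep/
  _exact.py           exact hypergeometric / Fisher / binomial tests (integer arithmetic)
  synthetic.py        generators with truth sets
  calling.py          run-based CNV calling, density filter, summaries, comparisons
  differentiation.py  locus clustering and differentiation flagging
  overlap.py          interval intersection and overlap summaries
  expression.py       CNV-expression association statistics
  sweep.py            heterozygosity, lnRH, standardization, region calls
  io.py               BED/GFF3/TSV/CSV readers and writers
  pipeline.py         end-to-end driver with run manifest
  cli.py              click subcommand CLI
tests/                pytest suite; test_acceptance.py covers the acceptance criteria
scripts/acceptance.py acceptance report generator
```
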