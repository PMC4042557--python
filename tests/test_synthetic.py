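import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from cnvsweep.calling import call_cnvs
from cnvsweep.sweep import expected_heterozygosity
from cnvsweep.synthetic import (
    ExprSimConfig,
    MicrosatSimConfig,
    Region,
    RegionSet,
    SimConfig,
    TruthCnv,
    generate_probe_layout,
    make_gene_models,
    random_regions,
    simulate_cgh,
    simulate_expression_stats,
    simulate_microsats,
)


class TestRegionSet:
    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError, match="start >= end"):
            RegionSet([Region("chr1", 100, 100, "g")], flank=0)
        with pytest.raises(ValueError, match="negative"):
            RegionSet([Region("chr1", -5, 100, "g")], flank=0)

    def test_flank_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap after flank"):
            RegionSet(
                [Region("chr1", 0, 1000, "a"), Region("chr1", 1500, 2500, "b")], flank=1000
            )


class TestProbeLayout:
    def test_ten_probes_for_1700bp(self):
        rs = RegionSet([Region("chr1", 0, 1700, "g")], flank=0)
        layout = generate_probe_layout(rs, spacing=170)
        assert len(layout.probes) == 10

    def test_minimum_one_probe(self):
        rs = RegionSet([Region("chr1", 0, 100, "g")], flank=0)
        layout = generate_probe_layout(rs, spacing=170)
        assert len(layout.probes) == 1

    def test_two_regions_five_each(self):
        rs = RegionSet(
            [Region("chr1", 0, 1000, "a"), Region("chr1", 5000, 6000, "b")], flank=0
        )
        layout = generate_probe_layout(rs, spacing=170)
        counts = layout.probes.groupby("region_id").size()
        assert counts["a"] == 5 and counts["b"] == 5

    def test_flank_extension_included(self):
        rs = RegionSet([Region("chr1", 10000, 11700, "g")], flank=1000)
        layout = generate_probe_layout(rs, spacing=170)
        assert len(layout.probes) == (1700 + 2000) // 170
        assert layout.probes["start"].min() == 9000

    def test_probes_inside_their_region(self):
        rs = RegionSet([Region("chr1", 0, 500, "g")], flank=0)
        layout = generate_probe_layout(rs, spacing=170)
        assert (layout.probes["end"] <= 500).all()

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError, match="empty region set"):
            generate_probe_layout(RegionSet([], flank=0))

    def test_spacing_below_probe_length_rejected(self):
        rs = RegionSet([Region("chr1", 0, 1000, "g")], flank=0)
        with pytest.raises(ValueError, match="probe length"):
            generate_probe_layout(rs, spacing=50)


def _one_region_layout(length=2000):
    rs = RegionSet([Region("chr1", 0, length, "g")], flank=0)
    return generate_probe_layout(rs, spacing=170)


class TestSimulateCgh:
    def test_heterozygous_deletion_shift(self):
        layout = _one_region_layout()
        # spans probes 2..6 (starts 340..850): 5 probes
        event = TruthCnv("pop1_s1", "chr1", 340, 910, copy_state=1)
        cfg = SimConfig(n_samples_per_pop=1, noise_sd=1e-12, seed=0)
        tracks, truths = simulate_cgh(layout, cfg, events=[event])
        track = [t for t in tracks if t.sample_id == "pop1_s1"][0]
        vals = track.probes["log2_ratio"].to_numpy()
        hit = (track.probes["start"] < 910) & (track.probes["end"] > 340)
        assert hit.sum() == 4
        assert np.allclose(vals[hit.to_numpy()], -1.0, atol=1e-6)
        assert np.allclose(vals[~hit.to_numpy()], 0.0, atol=1e-6)

    def test_three_copy_shift(self):
        assert TruthCnv("s", "chr1", 0, 100, copy_state=3).expected_shift == pytest.approx(0.585, abs=1e-3)

    def test_zero_copy_floor(self):
        assert TruthCnv("s", "chr1", 0, 100, copy_state=0).expected_shift == -3.0

    def test_copy_state_two_rejected(self):
        with pytest.raises(ValueError, match="copy_state"):
            TruthCnv("s", "chr1", 0, 100, copy_state=2)

    def test_determinism(self):
        layout = _one_region_layout()
        cfg = SimConfig(pop_frequencies=((0.5, 0.5), (0.2, 0.8)), seed=42)
        t1, tr1 = simulate_cgh(layout, cfg)
        t2, tr2 = simulate_cgh(layout, cfg)
        assert tr1 == tr2
        for a, b in zip(t1, t2):
            assert a.probes["log2_ratio"].equals(b.probes["log2_ratio"])

    def test_event_outside_layout_rejected(self):
        layout = _one_region_layout()
        bad = TruthCnv("pop1_s1", "chr9", 0, 100, copy_state=1)
        with pytest.raises(ValueError, match="outside the probe layout"):
            simulate_cgh(layout, SimConfig(n_samples_per_pop=1, noise_sd=1e-12), events=[bad])

    def test_truth_conservation(self, rng):
        # noise-free expectation equals the truth shift on covered probes, 0 elsewhere
        regions = random_regions(5, rng, flank=500, gene_length=(2000, 4000))
        layout = generate_probe_layout(regions)
        cfg = SimConfig(
            pop_frequencies=((1.0, 1.0), (1.0, 1.0)), copy_states=(1, 3),
            noise_sd=1e-12, seed=9,
        )
        tracks, truths = simulate_cgh(layout, cfg)
        for track in tracks:
            mine = [t for t in truths if t.sample_id == track.sample_id]
            expect = np.zeros(len(track.probes))
            for t in mine:
                mask = (
                    (track.probes["chrom"] == t.chrom)
                    & (track.probes["start"] < t.end)
                    & (track.probes["end"] > t.start)
                ).to_numpy()
                expect[mask] = t.expected_shift
            assert np.allclose(track.probes["log2_ratio"].to_numpy(), expect, atol=1e-6)

    def test_batch_inflation_raises_noise(self):
        layout = _one_region_layout(20000)
        cfg = SimConfig(
            n_samples_per_pop=2, noise_sd=0.1, batch_sd_inflation=5.0, batch_samples=(0,),
            seed=5,
        )
        tracks, _ = simulate_cgh(layout, cfg)
        sds = [t.probes["log2_ratio"].std() for t in tracks]
        assert sds[0] > 3 * sds[1]

    def test_recovery_from_injected_cnvs(self):
        # noise_sd 0.1, tau 0.5, |shift| >= 1: exact probe-set recovery, no false calls
        n_false = 0
        for rep in range(25):
            rng = np.random.default_rng(rep)
            layout = _one_region_layout(40_000)  # 235 probes
            starts = layout.probes["start"].to_numpy()
            i = int(rng.integers(0, len(starts) - 10))
            k = int(rng.integers(3, 9))
            event = TruthCnv(
                "pop1_s1", "chr1", int(starts[i]), int(starts[i + k - 1]) + 60,
                copy_state=int(rng.choice([0, 1, 4])),
            )
            cfg = SimConfig(n_samples_per_pop=1, noise_sd=0.1, seed=1000 + rep)
            tracks, _ = simulate_cgh(layout, cfg, events=[event])
            carrier = [t for t in tracks if t.sample_id == "pop1_s1"][0]
            clean = [t for t in tracks if t.sample_id != "pop1_s1"][0]
            calls = call_cnvs(carrier)
            assert len(calls) == 1
            (c,) = calls
            assert (c.start, c.end, c.n_probes) == (event.start, event.end, k)
            n_false += len(call_cnvs(clean))
        assert n_false == 0


class TestSimulateMicrosats:
    def test_ladder_constraint(self):
        cfg = MicrosatSimConfig(
            n_individuals_per_pop=10, n_neutral=5, n_candidate=1, motif=2,
            base_length=120, seed=1,
        )
        genotypes, _ = simulate_microsats(cfg)
        lengths = pd.concat([genotypes["allele1_bp"], genotypes["allele2_bp"]])
        assert ((lengths - 120) % 2 == 0).all()
        assert (lengths >= 120).all()

    def test_determinism(self):
        cfg = MicrosatSimConfig(n_individuals_per_pop=8, n_neutral=4, n_candidate=2, seed=7)
        g1, t1 = simulate_microsats(cfg)
        g2, t2 = simulate_microsats(cfg)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match=">= 2 individuals"):
            MicrosatSimConfig(n_individuals_per_pop=1)

    def test_neutral_construction_mean_zero(self):
        # sweep_factor 1: per-locus H difference between populations averages 0
        diffs = []
        for rep in range(200):
            cfg = MicrosatSimConfig(
                n_individuals_per_pop=20, n_neutral=4, n_candidate=0, seed=rep
            )
            genotypes, _ = simulate_microsats(cfg)
            for locus, g in genotypes.groupby("locus"):
                hs = {}
                for pop, gp in g.groupby("population"):
                    hs[pop] = expected_heterozygosity(
                        list(zip(gp["allele1_bp"], gp["allele2_bp"]))
                    )
                diffs.append(hs["pop1"] - hs["pop2"])
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se

    def test_swept_locus_loses_diversity(self):
        # Monte-Carlo under the generator itself: target-population H lower
        # than the other population's in >= 95% of 200 replicates
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = MicrosatSimConfig(
                n_individuals_per_pop=20, n_neutral=1, n_candidate=1,
                sweep_factor=0.05, swept_candidates=(0,), seed=50_000 + rep,
            )
            genotypes, _ = simulate_microsats(cfg)
            g = genotypes[genotypes["locus"] == "candidate_001"]
            hs = {
                pop: expected_heterozygosity(list(zip(gp["allele1_bp"], gp["allele2_bp"])))
                for pop, gp in g.groupby("population")
            }
            wins += hs["pop2"] < hs["pop1"]  # pop2 is the default swept population
        assert wins / n_rep >= 0.95

    def test_null_rank_test_uniform(self):
        # with sweep_factor 1, pop1-vs-pop2 H comparison is a true null
        pvals = []
        for rep in range(40):
            cfg = MicrosatSimConfig(
                n_individuals_per_pop=15, n_neutral=10, n_candidate=0, seed=900 + rep
            )
            genotypes, _ = simulate_microsats(cfg)
            h1, h2 = [], []
            for locus, g in genotypes.groupby("locus"):
                for pop, gp in g.groupby("population"):
                    h = expected_heterozygosity(list(zip(gp["allele1_bp"], gp["allele2_bp"])))
                    (h1 if pop == "pop1" else h2).append(h)
            pvals.append(st.mannwhitneyu(h1, h2).pvalue)
        assert sum(p < 0.05 for p in pvals) <= 8  # ~2 expected under the null


class TestSimulateExpression:
    @staticmethod
    def _genes(rng, n=60):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "cnv_sign": rng.choice([-1, 0, 1], size=n, p=[0.2, 0.6, 0.2]),
            }
        )

    def test_coupling_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="coupling"):
            simulate_expression_stats(self._genes(rng), coupling=1.5)

    def test_null_pvalues_uniform(self):
        passes = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            stats = simulate_expression_stats(
                self._genes(rng, 80), coupling=0.0,
                config=ExprSimConfig(de_fraction=0.0, seed=rep),
            )
            p = stats["p_value"].to_numpy()
            passes += st.kstest(p, "uniform").pvalue > 0.01
        assert passes / n_rep >= 0.95

    def test_full_coupling_matches_sign(self):
        concordant = discordant = 0
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            genes = self._genes(rng, 30)
            stats = simulate_expression_stats(
                genes, coupling=1.0,
                config=ExprSimConfig(de_fraction=0.0, effect=8.0, seed=rep),
            )
            merged = stats.merge(genes, on="gene_id")
            carriers = merged[(merged["cnv_sign"] != 0) & (merged["status"] == "DE")]
            agree = np.sign(carriers["t_statistic"]) == carriers["cnv_sign"]
            concordant += int(agree.sum())
            discordant += int((~agree).sum())
        assert concordant / (concordant + discordant) > 0.95

    def test_zero_coupling_no_size_correlation(self):
        rhos = []
        for rep in range(50):
            rng = np.random.default_rng(4000 + rep)
            genes = self._genes(rng, 50)
            genes["cnv_size"] = rng.integers(200, 10_000, size=50) * (genes["cnv_sign"] != 0)
            stats = simulate_expression_stats(genes, coupling=0.0,
                                              config=ExprSimConfig(seed=rep))
            sub = stats[(stats["tissue"] == "brain") & (stats["platform"] == "A")]
            merged = sub.merge(genes, on="gene_id")
            rhos.append(st.spearmanr(merged["cnv_size"], abs(merged["t_statistic"])).statistic)
        assert abs(np.mean(rhos)) < 0.05

    def test_determinism(self, rng):
        genes = self._genes(rng)
        a = simulate_expression_stats(genes, 0.5, ExprSimConfig(seed=11))
        b = simulate_expression_stats(genes, 0.5, ExprSimConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestGeneModels:
    def test_partition(self):
        rs = RegionSet([Region("chr1", 0, 10_000, "g")], flank=0)
        feats = make_gene_models(rs, exons_per_gene=3, exon_length=200)
        feats.sort(key=lambda f: f.start)
        assert feats[0].start == 0 and feats[-1].end == 10_000
        for a, b in zip(feats, feats[1:]):
            assert a.end == b.start  # no gaps, no overlap
        assert sum(f.length for f in feats) == 10_000

    def test_zero_internal_exons(self):
        rs = RegionSet([Region("chr1", 0, 2000, "g")], flank=0)
        feats = make_gene_models(rs, exons_per_gene=0, exon_length=300)
        classes = [f.feature_class for f in sorted(feats, key=lambda f: f.start)]
        assert classes == ["exon5", "intron", "exon3"]

    def test_exons_exceeding_gene_rejected(self):
        rs = RegionSet([Region("chr1", 0, 1000, "g")], flank=0)
        with pytest.raises(ValueError, match="exceed gene length"):
            make_gene_models(rs, exons_per_gene=5, exon_length=300)

    def test_bed_round_trip(self, tmp_path):
        from cnvsweep.io import read_features_bed, write_features_bed

        rs = RegionSet(
            [Region("chr1", 0, 8000, "gA"), Region("chr2", 100, 6100, "gB")], flank=0
        )
        feats = make_gene_models(rs, exons_per_gene=2, exon_length=150)
        path = tmp_path / "features.bed"
        write_features_bed(feats, path)
        assert read_features_bed(path) == feats
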