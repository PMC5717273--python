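import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import methkit as mk

from conftest import dummy_dmr, replace_config


class TestGenome:
    def test_fixed_seed_is_byte_identical(self, small_config):
        g1, genes1 = mk.simulate_genome(small_config)
        g2, genes2 = mk.simulate_genome(small_config)
        assert g1 == g2
        assert genes1 == genes2

    def test_gc_fraction_one_gives_only_gc(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=40_000, n_chroms=2, gc_fraction=1.0, n_dmrs=0, seed=1)
        genome, _ = mk.simulate_genome(cfg)
        assert set("".join(genome.values())) <= {"G", "C"}

    def test_gc_fraction_matches_config(self, small_dataset):
        seq = "".join(small_dataset.genome.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(small_dataset.config.gc_fraction, rel=0.02)

    def test_gene_structure_valid(self, small_dataset):
        for gene in small_dataset.genes:
            exons = gene.exons
            assert all(s <= e for s, e in exons)
            # introns are exactly the gaps between consecutive exons
            gaps = tuple(
                (a_end + 1, b_start - 1)
                for (_, a_end), (b_start, _) in zip(exons, exons[1:]))
            assert gene.introns == gaps
            assert gene.tss == (exons[0][0] if gene.strand == "+" else exons[-1][1])

    def test_too_short_genome_rejected(self):
        with pytest.raises(mk.MethylomeError, match="too short"):
            mk.simulate_genome(mk.SimulationConfig(
                genome_length_bp=8000, n_chroms=4, seed=0))


class TestTrueMethylome:
    def test_zero_noncg_rate_means_zero_noncg_levels(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=60_000, n_chroms=1, noncg_meth_rate=0.0,
            n_dmrs=0, seed=5)
        genome, _ = mk.simulate_genome(cfg)
        meth = mk.assign_true_methylome(genome, cfg)
        for tab in meth.sites.values():
            noncg = tab.loc[tab["context"] != "CG", "ml"]
            assert (noncg == 0.0).all()

    def test_zero_high_fraction_means_unmethylated_cg(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=60_000, n_chroms=1, cg_meth_high_fraction=0.0,
            noncg_meth_rate=0.0, n_dmrs=0, seed=5)
        genome, _ = mk.simulate_genome(cfg)
        meth = mk.assign_true_methylome(genome, cfg)
        assert all((tab["ml"] == 0.0).all() for tab in meth.sites.values())

    def test_realized_mc_fraction_matches_expectation(self):
        """Law of large numbers: genome-wide mean true ML ~= its expectation."""
        cfg = mk.SimulationConfig(
            genome_length_bp=1_000_000, n_chroms=1, n_dmrs=0, seed=11)
        genome, _ = mk.simulate_genome(cfg)
        meth = mk.assign_true_methylome(genome, cfg)
        tab = pd.concat(meth.sites.values())
        cg = tab["context"] == "CG"
        frac_cg = cg.mean()
        expected = (
            frac_cg * cfg.cg_meth_high_fraction * cfg.high_meth_beta_mean
            + (1 - frac_cg) * cfg.noncg_meth_rate
        )
        assert meth.mean_ml() == pytest.approx(expected, rel=0.10)


class TestPlanting:
    def test_regions_disjoint_and_cg_dense(self, small_dataset):
        truth = small_dataset.truth
        by_chrom = {}
        for t in truth:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
        for regions in by_chrom.values():
            regions.sort()
            for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
                assert e1 < s2

    def test_zero_baseline_hyper_region_hits_delta(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=100_000, n_chroms=1, cg_meth_high_fraction=0.0,
            noncg_meth_rate=0.0, n_dmrs=3, dmr_delta=0.4,
            dmr_hyper_fraction=1.0, seed=2)
        genome, _ = mk.simulate_genome(cfg)
        base = mk.assign_true_methylome(genome, cfg)
        meth_a, meth_b, truth = mk.plant_dmrs(base, cfg)
        assert len(truth) == 3
        for t in truth:
            tab_a = meth_a.sites[t.chrom]
            tab_b = meth_b.sites[t.chrom]
            inside = (tab_a["pos"] >= t.start) & (tab_a["pos"] <= t.end)
            assert (tab_a.loc[inside, "ml"] == 0.4).all()
            assert (tab_b.loc[inside, "ml"] == 0.0).all()

    def test_hypo_regions_raise_group_b(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=100_000, n_chroms=1, cg_meth_high_fraction=0.0,
            noncg_meth_rate=0.0, n_dmrs=3, dmr_delta=0.3,
            dmr_hyper_fraction=0.0, seed=2)
        genome, _ = mk.simulate_genome(cfg)
        meth_a, meth_b, truth = mk.plant_dmrs(
            mk.assign_true_methylome(genome, cfg), cfg)
        for t in truth:
            assert t.direction == "hypo"
            inside_b = meth_b.sites[t.chrom]["pos"].between(t.start, t.end)
            assert (meth_b.sites[t.chrom].loc[inside_b, "ml"] == 0.3).all()

    def test_impossible_placement_rejected(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=40_000, n_chroms=1, n_dmrs=50, seed=2)
        genome, _ = mk.simulate_genome(cfg)
        with pytest.raises(mk.MethylomeError, match="place"):
            mk.plant_dmrs(mk.assign_true_methylome(genome, cfg), cfg)


class TestEmission:
    def test_no_methylation_no_conversion_failure_gives_zero_counts(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=50_000, n_chroms=1, cg_meth_high_fraction=0.0,
            noncg_meth_rate=0.0, nonconversion_rate=0.0, n_dmrs=0, seed=3)
        genome, _ = mk.simulate_genome(cfg)
        sample = mk.emit_counts(
            mk.assign_true_methylome(genome, cfg), cfg, cfg.rng("counts_a"))
        assert (sample.df["n_meth"] == 0).all()

    def test_full_methylation_gives_all_meth_reads(self):
        cfg = mk.SimulationConfig(
            genome_length_bp=50_000, n_chroms=1, cg_meth_high_fraction=0.0,
            noncg_meth_rate=1.0, nonconversion_rate=0.0, n_dmrs=0, seed=3)
        genome, _ = mk.simulate_genome(cfg)
        meth = mk.assign_true_methylome(genome, cfg)
        for tab in meth.sites.values():  # force ml=1 everywhere
            tab["ml"] = 1.0
        sample = mk.emit_counts(meth, cfg, cfg.rng("counts_a"))
        assert (sample.df["n_unmeth"] == 0).all()

    def test_unconverted_read_expectation(self):
        """With ml=0 the unconverted fraction converges to r."""
        cfg = mk.SimulationConfig(
            genome_length_bp=200_000, n_chroms=1, cg_meth_high_fraction=0.0,
            noncg_meth_rate=0.0, nonconversion_rate=0.0015, n_dmrs=0, seed=3)
        genome, _ = mk.simulate_genome(cfg)
        sample = mk.emit_counts(
            mk.assign_true_methylome(genome, cfg), cfg, cfg.rng("counts_a"))
        total = int(sample.df["n_meth"].sum() + sample.df["n_unmeth"].sum())
        observed = int(sample.df["n_meth"].sum())
        lo, hi = sps.binom.interval(0.999, total, 0.0015)
        assert lo <= observed <= hi

    def test_lambda_r_zero_all_unmethylated(self):
        cfg = mk.SimulationConfig(nonconversion_rate=0.0, seed=4)
        lam = mk.emit_lambda(cfg, cfg.rng("lambda_a"))
        assert (lam.df["n_meth"] == 0).all()
        assert set(lam.df["chrom"]) == {"lambda"}

    def test_lambda_r_half_splits_reads(self):
        cfg = mk.SimulationConfig(nonconversion_rate=0.5, seed=4)
        lam = mk.emit_lambda(cfg, cfg.rng("lambda_a"))
        frac = lam.df["n_meth"].sum() / (
            lam.df["n_meth"].sum() + lam.df["n_unmeth"].sum())
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_lambda_reproducible(self):
        cfg = mk.SimulationConfig(seed=4)
        a = mk.emit_lambda(cfg, cfg.rng("lambda_a"))
        b = mk.emit_lambda(cfg, cfg.rng("lambda_a"))
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_dataset_deterministic(self, small_config, small_dataset):
        again = mk.simulate_dataset(small_config)
        pd.testing.assert_frame_equal(again.sample_a.df, small_dataset.sample_a.df)
        pd.testing.assert_frame_equal(again.sample_b.df, small_dataset.sample_b.df)
        assert again.truth == small_dataset.truth
        assert again.genome == small_dataset.genome

    def test_write_dataset_files(self, tmp_path, small_dataset):
        mk.write_dataset(small_dataset, tmp_path)
        for name in ("genome.fa", "genes.gff3", "groupA.cx.tsv", "groupB.cx.tsv",
                     "lambdaA.cx.tsv", "lambdaB.cx.tsv", "truth.bed", "config.yaml"):
            assert (tmp_path / name).exists()
        cfg = mk.SimulationConfig.from_yaml(tmp_path / "config.yaml")
        assert cfg == small_dataset.config


class TestEvaluateCalls:
    def test_perfect_calls(self):
        truth = [mk.TruthRegion("c1", 100, 1100, "hyper", 0.3)]
        calls = [dummy_dmr("c1", 100, 1100)]
        ev = mk.evaluate_calls(calls, truth)
        assert ev.sensitivity == 1.0 and ev.precision == 1.0

    def test_no_calls_zero_sensitivity(self):
        truth = [mk.TruthRegion("c1", 100, 1100, "hyper", 0.3)]
        ev = mk.evaluate_calls([], truth)
        assert ev.sensitivity == 0.0
        assert np.isnan(ev.precision)

    def test_half_overlap_recovers_at_quarter_threshold(self):
        truth = [mk.TruthRegion("c1", 1001, 2000, "hyper", 0.3)]
        calls = [dummy_dmr("c1", 1501, 2600)]  # covers half the truth
        assert mk.evaluate_calls(calls, truth, 0.25).sensitivity == 1.0
        assert mk.evaluate_calls(calls, truth, 0.75).sensitivity == 0.0

    def test_empty_truth_is_error(self):
        with pytest.raises(mk.MethylomeError, match="undefined"):
            mk.evaluate_calls([dummy_dmr("c1", 1, 100)], [])
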