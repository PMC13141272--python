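"""The synthetic-data generator: determinism, ground-truth structure, and the
spike-in composition model."""

import filecmp
from copy import deepcopy
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import k4gauge as kg
from k4gauge.simulate import (DegParams, SimConfig, derive_double_mutant,
                              expected_intensity, spike_read_fraction, stream)


class TestFeatures:
    def test_deterministic_given_seed(self, small_genome):
        a = kg.simulate_features(small_genome, 100, 50, seed=1)
        b = kg.simulate_features(small_genome, 100, 50, seed=1)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_zero_counts_valid(self, small_genome):
        tss, enh = kg.simulate_features(small_genome, 0, 5, seed=1)
        assert len(tss) == 0 and len(enh) == 5

    def test_too_many_features_rejected(self, small_genome):
        with pytest.raises(ValueError, match="genome too small"):
            kg.simulate_features(small_genome, 10**6, 0, seed=1)

    def test_edge_clearance(self, small_genome, features):
        tss, enh = features
        for df in (tss, enh):
            for _, row in df.iterrows():
                length = small_genome.length(row["chrom"])
                assert row["start"] >= 5000 and row["end"] <= length - 5000


class TestCoverage:
    def test_unknown_mark_and_genotype_rejected(self, small_genome, features, config):
        tss, enh = features
        with pytest.raises(ValueError, match="unknown mark"):
            kg.simulate_coverage(small_genome, tss, enh, "me4", "wt", config)
        with pytest.raises(ValueError, match="mark_effects"):
            kg.simulate_coverage(small_genome, tss, enh, "me3", "nope", config)

    def test_zero_factors_leave_only_background(self, small_genome, features):
        """With all genotype factors at zero, feature bins carry only noise:
        their mean matches background within sampling error over seeds."""
        tss, enh = features
        diffs = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, depth=200_000)
            track = kg.simulate_coverage(small_genome, tss, enh, "me2", "rbbp5", cfg)
            zero_cfg = replace(cfg, mark_effects={
                **cfg.mark_effects, "rbbp5": {m: {"tss": 0.0, "enhancer": 0.0}
                                              for m in ("me1", "me2", "me3")}})
            track = kg.simulate_coverage(small_genome, tss, enh, "me2", "rbbp5", zero_cfg)
            lam = expected_intensity(small_genome, tss, enh, "me2", "wt", zero_cfg)
            feat = np.concatenate([track.values[c][lam[c] > 2.0] for c in lam])
            bg = np.concatenate([track.values[c][lam[c] <= 2.0] for c in lam])
            diffs.append(feat.mean() - bg.mean())
        assert abs(np.mean(diffs)) < 0.05

    def test_unit_factors_match_wild_type_statistically(self, small_genome, features):
        tss, enh = features
        feat_means = {"wt": [], "clone": []}
        for seed in range(10):
            cfg = SimConfig(seed=seed, depth=200_000)
            cfg = replace(cfg, mark_effects={
                **cfg.mark_effects,
                "clone": deepcopy(cfg.mark_effects["wt"])})
            lam = expected_intensity(small_genome, tss, enh, "me3", "wt", cfg)
            for g in ("wt", "clone"):
                track = kg.simulate_coverage(small_genome, tss, enh, "me3", g, cfg)
                feat_means[g].append(
                    np.concatenate([track.values[c][lam[c] > 2.0] for c in lam]).mean())
        wt, clone = np.array(feat_means["wt"]), np.array(feat_means["clone"])
        # same expected intensity: per-seed relative difference is small noise
        assert np.abs(wt.mean() - clone.mean()) / wt.mean() < 0.02


class TestSpikeModel:
    def test_equal_depletion_equal_expectation(self):
        totals = np.zeros(2)
        for seed in range(30):
            t = kg.simulate_spikein_counts({"a": 1.0, "b": 1.0},
                                           {"a": 10**6, "b": 10**6}, 0.05, seed)
            totals += t.set_index("sample_id")["spike_reads"].loc[["a", "b"]].to_numpy()
        assert abs(totals[0] - totals[1]) / totals.mean() < 0.02

    def test_half_depletion_doubles_spike_share(self):
        """Monte-Carlo mean matches the composition model's analytic value."""
        expected_ratio = spike_read_fraction(0.5, 0.05) / spike_read_fraction(1.0, 0.05)
        ratios = []
        for seed in range(50):
            t = kg.simulate_spikein_counts({"dep": 0.5, "ref": 1.0},
                                           {"dep": 10**6, "ref": 10**6}, 0.05, seed)
            s = t.set_index("sample_id")["spike_reads"]
            ratios.append(s["dep"] / s["ref"])
        assert np.mean(ratios) == pytest.approx(expected_ratio, rel=0.01)
        assert expected_ratio == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("depletion,depth", [(-0.1, 10**6), (1.5, 10**6), (1.0, 0)])
    def test_invalid_inputs_rejected(self, depletion, depth):
        with pytest.raises(ValueError):
            kg.simulate_spikein_counts({"a": depletion}, {"a": depth}, 0.05, seed=0)

    def test_no_depletion_converges_to_equal_shares(self):
        """As depletion -> 1 everywhere at equal depth, spike shares equalise."""
        shares = []
        for seed in range(50):
            t = kg.simulate_spikein_counts({s: 1.0 for s in "abc"},
                                           {s: 500_000 for s in "abc"}, 0.05, seed)
            spike = t["spike_reads"].to_numpy(dtype=float)
            shares.append(spike / spike.sum())
        mean_shares = np.mean(shares, axis=0)
        assert np.all(np.abs(mean_shares - 1 / 3) / (1 / 3) < 0.05)


class TestDegTable:
    def test_exact_label_counts(self, small_genome):
        cfg = SimConfig(seed=7, deg_params=DegParams(n_genes=1000, frac_up=0.1,
                                                     frac_down=0.05))
        table = kg.simulate_deg_table(cfg, small_genome)
        counts = table["sim_label"].value_counts()
        assert counts["up"] == 100 and counts["down"] == 50

    def test_null_only_table_has_no_deg_at_thresholds(self, small_genome):
        cfg = SimConfig(seed=3, deg_params=DegParams(n_genes=2000, frac_up=0.0,
                                                     frac_down=0.0))
        call = kg.call_deg(kg.simulate_deg_table(cfg, small_genome))
        assert len(call.deg) == 0

    def test_x_fraction_within_binomial_ci(self, small_genome):
        cfg = SimConfig(seed=5, deg_params=DegParams(n_genes=10_000,
                                                     x_gene_fraction=0.2))
        table = kg.simulate_deg_table(cfg, small_genome)
        share = (table["chrom"] == "chrX").mean()
        assert abs(share - 0.2) < 0.02  # ~5 sd of Binomial(10000, 0.2)/10000

    def test_internal_consistency(self, small_genome, config):
        table = kg.simulate_deg_table(config, small_genome)
        np.testing.assert_allclose(table["baseMean"],
                                   (table["baseMeanA"] + table["baseMeanB"]) / 2)
        np.testing.assert_allclose(table["log2FoldChange"],
                                   np.log2(table["baseMeanB"] / table["baseMeanA"]))

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError):
            DegParams(frac_up=0.7, frac_down=0.5)

    def test_double_mutant_restores_a_fraction(self, small_genome, config):
        single = kg.simulate_deg_table(config, small_genome)
        double = derive_double_mutant(single, config, restored_fraction=0.2)
        single_deg = set(single.loc[single["sim_label"] != "null", "gene_id"])
        double_null = set(double.loc[double["sim_label"] == "null", "gene_id"])
        restored = single_deg & double_null
        assert len(restored) == round(0.2 * len(single_deg))
        # per-condition means stay consistent after the rewrite
        np.testing.assert_allclose(double["log2FoldChange"],
                                   np.log2(double["baseMeanB"] / double["baseMeanA"]))


class TestStreamsAndFixtures:
    def test_named_streams_are_independent(self):
        a1 = stream(42, "alpha").random(5)
        b = stream(42, "beta").random(5)
        a2 = stream(42, "alpha").random(5)
        np.testing.assert_array_equal(a1, a2)
        assert not np.allclose(a1, b)

    def test_fixtures_byte_identical_and_parseable(self, tmp_path):
        import k4gauge.io as kio
        genome = kg.default_toy_genome(100_000)
        cfg = SimConfig(seed=9, depth=100_000,
                        deg_params=DegParams(n_genes=500))
        m1 = kg.write_fixtures(tmp_path / "a", cfg, genome=genome, n_tss=20, n_enh=10)
        m2 = kg.write_fixtures(tmp_path / "b", cfg, genome=genome, n_tss=20, n_enh=10)
        assert len(m1) >= 6
        for key in m1:
            assert filecmp.cmp(m1[key], m2[key], shallow=False), key
        g = kio.read_chrom_sizes(m1["chrom_sizes"])
        assert g.chromosomes == genome.chromosomes
        track = kio.read_bedgraph(m1["track_wt_me3"], g, bin_size=cfg.bin_size)
        track.validate_against(g)
        peaks = kio.read_broadpeak(m1["peaks_wt_me3"])
        assert (peaks["end"] > peaks["start"]).all()
        deg = kio.read_table(m1["deg_wdr5"])
        kg.call_deg(deg)

    def test_empty_feature_set_writes_valid_empty_bed(self, tmp_path):
        import k4gauge.io as kio
        tss, _ = kg.simulate_features(kg.default_toy_genome(100_000), 0, 0, seed=0)
        path = tmp_path / "empty.bed"
        kio.write_bed(tss, path)
        assert len(kio.read_bed(path)) == 0
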