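"""DEG calling, the net-change metric, rank tests, enrichment and qPCR."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import k4gauge as kg
from k4gauge.stats import mann_whitney, u_statistic
from k4gauge.transcriptome import harmonize_universe


def deg_table(rows):
    defaults = {"chrom": "chrI", "baseMean": 100.0, "baseMeanA": 100.0,
                "baseMeanB": 100.0, "log2FoldChange": 0.0, "padj": 1.0}
    out = []
    for i, row in enumerate(rows):
        d = dict(defaults, gene_id=f"g{i}")
        d.update(row)
        out.append(d)
    return pd.DataFrame(out)


def call_of(labels):
    return kg.DEGCall(pd.Series(list(labels.values()),
                                index=pd.Index(list(labels), name="gene_id")))


class TestCallDeg:
    @pytest.mark.parametrize("row,expected", [
        ({"log2FoldChange": 1.5, "padj": 0.01}, "up"),
        ({"log2FoldChange": -1.5, "padj": 0.01}, "down"),
        ({"log2FoldChange": 1.0, "padj": 0.001}, "unchanged"),     # strict >
        ({"log2FoldChange": 2.0, "padj": 0.05}, "unchanged"),      # strict <
        ({"log2FoldChange": 2.0, "padj": np.nan}, "unchanged"),    # missing padj
    ])
    def test_threshold_rules(self, row, expected):
        call = kg.call_deg(deg_table([row]))
        assert call.calls.iloc[0] == expected

    def test_expression_floor_either_condition(self):
        table = deg_table([
            {"baseMeanA": 10.0, "baseMeanB": 30.0, "log2FoldChange": 2.0,
             "padj": 1e-5},                                  # both below 50: excluded
            {"baseMeanA": 10.0, "baseMeanB": 60.0, "log2FoldChange": 2.0,
             "padj": 1e-5},                                  # mutant above 50: in
        ])
        call = kg.call_deg(table)
        assert "g0" not in call.universe
        assert call.calls["g1"] == "up"

    def test_order_invariant_counts(self):
        rng = np.random.default_rng(0)
        table = deg_table([{"log2FoldChange": float(rng.normal(0, 2)),
                            "padj": float(rng.uniform(0, 1))} for _ in range(200)])
        a = kg.call_deg(table).counts()
        b = kg.call_deg(table.iloc[::-1].reset_index(drop=True)).counts()
        assert a == b


class TestNetChange:
    def test_two_gene_forced_example(self):
        table = deg_table([{"baseMean": 100.0, "log2FoldChange": 1.0},
                           {"baseMean": 300.0, "log2FoldChange": -1.0}])
        call = call_of({"g0": "up", "g1": "down"})
        assert kg.net_transcriptome_change(call, table) == pytest.approx(-50.0)

    def test_single_gene_not_bounded_by_100(self):
        table = deg_table([{"baseMean": 10.0, "log2FoldChange": 2.0}])
        call = call_of({"g0": "up"})
        assert kg.net_transcriptome_change(call, table) == pytest.approx(200.0)

    def test_symmetric_set_is_zero(self):
        table = deg_table([{"baseMean": 50.0, "log2FoldChange": 1.5},
                           {"baseMean": 50.0, "log2FoldChange": -1.5}])
        call = call_of({"g0": "up", "g1": "down"})
        assert kg.net_transcriptome_change(call, table) == pytest.approx(0.0)

    def test_no_deg_rejected(self):
        table = deg_table([{}])
        with pytest.raises(ValueError, match="no DEG"):
            kg.net_transcriptome_change(call_of({"g0": "unchanged"}), table)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariance_to_order_and_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        n = 20
        table = deg_table([{"baseMean": float(rng.uniform(10, 1000)),
                            "log2FoldChange": float(rng.normal(0, 2))}
                           for _ in range(n)])
        call = call_of({f"g{i}": ("up" if i % 2 else "down") for i in range(n)})
        base = kg.net_transcriptome_change(call, table)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        rescaled = table.assign(baseMean=table["baseMean"] * scale)
        assert kg.net_transcriptome_change(call, shuffled) == pytest.approx(base)
        assert kg.net_transcriptome_change(call, rescaled) == pytest.approx(base)


class TestMannWhitney:
    def test_hand_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        res = mann_whitney([5, 5, 5], [5, 5, 5])
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 7) for m in range(n, 7)])
    def test_exact_agrees_with_scipy_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        x = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free values
        a, b = x[:n], x[n:]
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.method == "exact"
        assert ours.u == pytest.approx(float(ref.statistic))
        assert ours.p == pytest.approx(float(ref.pvalue))

    def test_exact_handles_ties_via_permutation_null(self):
        # permutation null conditional on values: brute-force over label splits
        a, b = np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0])
        ours = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        us = [u_statistic(pooled[list(ix)],
                          np.delete(pooled, list(ix)))
              for ix in combinations(range(5), 3)]
        u_obs = u_statistic(a, b)
        lower = np.mean([u <= u_obs + 1e-9 for u in us])
        upper = np.mean([u >= u_obs - 1e-9 for u in us])
        assert ours.p == pytest.approx(min(1.0, 2 * min(lower, upper)))

    def test_asymptotic_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(100):
            a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
            exact = mann_whitney(a, b, exact_max_n=8).p
            approx = mann_whitney(a, b, exact_max_n=0).p
            diffs.append(abs(exact - approx))
        assert max(diffs) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBaselineStratifiedTest:
    def test_down_genes_higher_baseline_detected(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            rows.append({"baseMeanA": float(rng.lognormal(7, 0.3)),
                         "log2FoldChange": -2.0, "padj": 0.001})
        for i in range(40):
            rows.append({"baseMeanA": float(rng.lognormal(4, 0.3)),
                         "log2FoldChange": 2.0, "padj": 0.001})
        for i in range(40):
            rows.append({"baseMeanA": float(rng.lognormal(5, 0.3))})
        table = deg_table(rows)
        call = kg.call_deg(table)
        out = kg.baseline_stratified_test(call, table).set_index("contrast")
        assert out.loc["down_vs_up", "p"] < 0.01

    def test_empty_category_named(self):
        table = deg_table([{"log2FoldChange": 2.0, "padj": 0.01}, {}])
        call = kg.call_deg(table)
        with pytest.raises(ValueError, match="down"):
            kg.baseline_stratified_test(call, table)


class TestChromosomeEnrichment:
    def test_forced_log2_value(self, small_genome):
        # 40 of 100 DEG on a chromosome holding 20% of the universe -> log2 = 1
        rows = []
        chroms = ["chrX"] * 200 + ["chrI"] * 800
        for i, c in enumerate(chroms):
            up = (c == "chrX" and i < 40) or (c == "chrI" and 240 <= i < 300)
            rows.append({"chrom": c,
                         "log2FoldChange": 2.0 if up else 0.0,
                         "padj": 0.001 if up else 0.9})
        table = deg_table(rows)
        call = kg.call_deg(table)
        out = kg.chromosome_enrichment(call, table, small_genome, "up")
        out = out.set_index("chrom")
        assert out.loc["chrX", "observed"] == 40
        assert out.loc["chrX", "log2_obs_exp"] == pytest.approx(1.0)
        assert out.loc["chrX", "ci_low"] < 1.0 < out.loc["chrX", "ci_high"]

    def test_flag_rule_is_dual(self, small_genome):
        rng = np.random.default_rng(2)
        chroms = rng.choice(small_genome.names, 3000)
        up = rng.random(3000) < 0.1  # uniform across chromosomes
        table = deg_table([{"chrom": c, "log2FoldChange": 2.0 if u else 0.0,
                            "padj": 0.001 if u else 0.9}
                           for c, u in zip(chroms, up)])
        call = kg.call_deg(table)
        out = kg.chromosome_enrichment(call, table, small_genome, "up")
        flagged_rule = (out["fdr"] <= 0.01) & (out["log2_obs_exp"].abs() >= np.log2(1.2))
        assert (out["flagged"] == flagged_rule).all()

    def test_unknown_direction_rejected(self, small_genome):
        table = deg_table([{"log2FoldChange": 2.0, "padj": 0.01}])
        with pytest.raises(ValueError):
            kg.chromosome_enrichment(kg.call_deg(table), table, small_genome, "sideways")


class TestSetLogic:
    def universe_calls(self, a, b, n=1000):
        genes = [f"g{i}" for i in range(n)]
        ca = {g: ("up" if g in a else "unchanged") for g in genes}
        cb = {g: ("up" if g in b else "unchanged") for g in genes}
        return call_of(ca), call_of(cb)

    def test_disjoint_and_identical(self):
        a = {f"g{i}" for i in range(50)}
        b = {f"g{i}" for i in range(50, 100)}
        ca, cb = self.universe_calls(a, b)
        out = kg.overlap_sets({"A": ca, "B": cb})
        assert out["overlap"].iloc[0] == 0
        ca, cb = self.universe_calls(a, a)
        out = kg.overlap_sets({"A": ca, "B": cb})
        assert out["overlap"].iloc[0] == 50
        assert out["p"].iloc[0] == pytest.approx(
            float(sps.hypergeom.sf(49, 1000, 50, 50)))

    def test_hypergeometric_tail_oracle(self):
        a = {f"g{i}" for i in range(50)}
        b = {f"g{i}" for i in range(40, 90)}  # overlap 10
        ca, cb = self.universe_calls(a, b)
        out = kg.overlap_sets({"A": ca, "B": cb})
        # exact tail sum oracle
        expected = sum(sps.hypergeom.pmf(k, 1000, 50, 50) for k in range(10, 51))
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_differing_universes_rejected(self):
        ca, _ = self.universe_calls(set(), set(), n=10)
        cb, _ = self.universe_calls(set(), set(), n=12)
        with pytest.raises(ValueError, match="universe"):
            kg.overlap_sets({"A": ca, "B": cb})
        fixed = harmonize_universe({"A": ca, "B": cb})
        kg.overlap_sets(fixed)  # intersected universes no longer raise

    def test_restored_genes(self):
        single = call_of({"a": "up", "b": "up", "c": "down", "d": "unchanged"})
        double = call_of({"a": "up", "b": "down", "c": "unchanged", "d": "unchanged"})
        restored, frac = kg.restored_genes(single, double)
        assert set(restored) == {"c"}
        assert frac == pytest.approx(1 / 3)
        same, frac0 = kg.restored_genes(single, single)
        assert len(same) == 0 and frac0 == 0.0


class TestCooks:
    def toy_table(self):
        return deg_table([
            {"cooks_rep1": 1.5, "log2FoldChange": 1.2, "padj": 0.01,
             "baseMeanA": 100.0, "baseMeanB": 100.0},
            {"cooks_rep1": 1.5, "log2FoldChange": 0.2, "padj": 0.9,
             "baseMeanA": 100.0, "baseMeanB": 100.0},
            {"cooks_rep1": 0.5, "log2FoldChange": 3.0, "padj": 0.001,
             "baseMeanA": 100.0, "baseMeanB": 100.0},
            {"cooks_rep1": 2.0, "log2FoldChange": 3.0, "padj": 0.001,
             "baseMeanA": 10.0, "baseMeanB": 10.0},   # fails expression filter
            {"cooks_rep1": 0.2, "log2FoldChange": 0.0, "padj": 0.9,
             "baseMeanA": 100.0, "baseMeanB": 100.0},
        ])

    def test_toy_counts(self):
        out = kg.cooks_sensitivity(self.toy_table(), "rep1")
        assert out == {"n_sensitive": 2, "n_standard": 1, "n_relaxed": 1}

    def test_no_outliers(self):
        table = self.toy_table()
        table["cooks_rep1"] = 0.1
        out = kg.cooks_sensitivity(table, "rep1")
        assert out == {"n_sensitive": 0, "n_standard": 0, "n_relaxed": 0}

    def test_relaxed_contains_standard(self, small_genome, config):
        table = kg.simulate_deg_table(config, small_genome, cooks_replicate="rep1",
                                      cooks_outlier_frac=0.1)
        out = kg.cooks_sensitivity(table, "rep1")
        assert out["n_relaxed"] >= out["n_standard"]

    def test_unknown_replicate_rejected(self):
        with pytest.raises(ValueError, match="rep9"):
            kg.cooks_sensitivity(self.toy_table(), "rep9")


class TestDdct:
    def ct(self, rows):
        return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])

    def test_worked_example_fold_four(self):
        table = self.ct([("t", "wt", 1, 20.0), ("t", "mut", 1, 18.0),
                         ("act-1", "wt", 1, 15.0), ("act-1", "mut", 1, 15.0)])
        out = kg.ddct(table, control_condition="wt")
        assert out["fold"].iloc[0] == pytest.approx(4.0)

    def test_identical_conditions_fold_one(self):
        table = self.ct([("t", "wt", 1, 21.0), ("t", "mut", 1, 21.0),
                         ("act-1", "wt", 1, 15.0), ("act-1", "mut", 1, 15.0)])
        assert kg.ddct(table, control_condition="wt")["fold"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_up_halves_expression(self):
        table = self.ct([("t", "wt", 1, 20.0), ("t", "mut", 1, 21.0),
                         ("act-1", "wt", 1, 15.0), ("act-1", "mut", 1, 15.0)])
        assert kg.ddct(table, control_condition="wt")["fold"].iloc[0] == pytest.approx(0.5)

    def test_replicate_sem_propagated(self):
        table = self.ct([("t", "wt", r, 20.0 + d) for r, d in [(1, -0.2), (2, 0.0), (3, 0.2)]]
                        + [("t", "mut", r, 18.0) for r in (1, 2, 3)]
                        + [("act-1", c, r, 15.0) for c in ("wt", "mut") for r in (1, 2, 3)])
        out = kg.ddct(table, control_condition="wt")
        assert out["sem_ddct"].iloc[0] > 0
        assert out["fold_low"].iloc[0] < out["fold"].iloc[0] < out["fold_high"].iloc[0]

    def test_missing_reference_rejected(self):
        table = self.ct([("t", "wt", 1, 20.0), ("t", "mut", 1, 18.0),
                         ("act-1", "wt", 1, 15.0)])
        with pytest.raises(ValueError, match="reference"):
            kg.ddct(table, control_condition="wt")
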