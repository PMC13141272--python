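"""Simulation experiments with known ground truth.

Each function runs one self-contained validation study over the synthetic
generator and the pipeline: recovery of a known global depletion by spike-in
normalisation (against a plain-CPM negative control), the sign of the net
transcriptome change under the study's expression structure, calibration and
power of the chromosome-level tests.  The analysis drivers, the test suite
and the acceptance script all call these, so the numbers they report are
recomputed from scratch each run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import (call_deg, chromosome_enrichment, cpm_normalise, default_toy_genome,
               net_transcriptome_change, normalise_experiment, simulate_coverage,
               simulate_deg_table, simulate_features, simulate_spikein_counts,
               weighted_chisq_uniformity)
from .genome import GenomeModel
from .simulate import (MARKS, DegParams, SimConfig, effective_ip_material,
                       expected_intensity)


def spike_recovery(true_depletion: float, n_seeds: int = 20, seed0: int = 0,
                   depth_wt: int = 2_000_000, depth_mut: int = 1_000_000,
                   genome: GenomeModel | None = None, mark: str = "me3",
                   n_tss: int = 60, n_enh: int = 30) -> dict[str, float]:
    """Recover a known global depletion through the spike-in pipeline.

    Simulates a wild-type and a globally depleted sample at a 2x sequencing
    depth imbalance, runs spike-in counting, factor derivation, downsampling
    and common-scale CPM, and measures the background-subtracted feature
    signal ratio.  The negative control repeats the measurement on plain
    per-sample CPM tracks, which normalise composition away and miss the
    depletion.
    """
    genome = default_toy_genome(300_000) if genome is None else genome
    recovered, naive = [], []
    for k in range(n_seeds):
        seed = seed0 + k
        cfg = SimConfig(seed=seed)
        eff = {**cfg.mark_effects,
               "mut": {m: {"tss": true_depletion, "enhancer": true_depletion}
                       for m in MARKS}}
        cfg = replace(cfg, mark_effects=eff)
        tss, enh = simulate_features(genome, n_tss, n_enh, seed=seed)
        wt_material = effective_ip_material(genome, tss, enh, mark, "wt", cfg)
        f_mut = effective_ip_material(genome, tss, enh, mark, "mut", cfg) / wt_material
        spike = simulate_spikein_counts({"wt": 1.0, "mut": f_mut},
                                        {"wt": depth_wt, "mut": depth_mut},
                                        cfg.spike_fraction, seed=seed)
        tracks = {
            row["sample_id"]: simulate_coverage(
                genome, tss, enh, mark, row["sample_id"], cfg,
                depth=int(row["target_reads"]))
            for _, row in spike.iterrows()}
        lam = expected_intensity(genome, tss, enh, mark, "wt", cfg)
        feat = {c: lam[c] > 2.0 for c in lam}

        def signal(track) -> float:
            f = np.concatenate([np.asarray(track.values[c], float)[feat[c]]
                                for c in feat])
            b = np.concatenate([np.asarray(track.values[c], float)[~feat[c]]
                                for c in feat])
            return f.mean() - b.mean()

        norm = normalise_experiment(tracks, spike, seed=seed, group_by=None)
        recovered.append(signal(norm["mut"]) / signal(norm["wt"]))
        plain = {s: cpm_normalise(t) for s, t in tracks.items()}
        naive.append(signal(plain["mut"]) / signal(plain["wt"]))
    return {"true": true_depletion,
            "recovered_mean": float(np.mean(recovered)),
            "naive_mean": float(np.mean(naive)),
            "recovered_rel_err": float(abs(np.mean(recovered) - true_depletion)
                                       / true_depletion),
            "naive_rel_err": float(abs(np.mean(naive) - true_depletion)
                                   / true_depletion),
            "n_seeds": n_seeds}


def net_change_directionality(n_sims: int = 100, seed0: int = 0,
                              params: DegParams | None = None,
                              genome: GenomeModel | None = None) -> dict[str, float]:
    """Sign of the net transcriptome change under the study's DEG structure.

    Tables are drawn with more up- than down-regulated genes but with
    down-regulated genes at higher wild-type expression; the net change
    should come out negative essentially always.
    """
    genome = default_toy_genome(300_000) if genome is None else genome
    params = DegParams() if params is None else params
    values = []
    for k in range(n_sims):
        cfg = SimConfig(seed=seed0 + k, deg_params=params)
        table = simulate_deg_table(cfg, genome)
        call = call_deg(table)
        counts = call.counts()
        values.append({"net": net_transcriptome_change(call, table),
                       "n_up": counts["up"], "n_down": counts["down"]})
    df = pd.DataFrame(values)
    return {"n_sims": n_sims,
            "frac_negative": float((df["net"] < 0).mean()),
            "frac_more_up_than_down": float((df["n_up"] > df["n_down"]).mean()),
            "net_mean": float(df["net"].mean())}


def chisq_calibration(n_reps: int = 2000, n_counts: int = 100_000,
                      seed: int = 0, genome: GenomeModel | None = None,
                      alpha: float = 0.05) -> dict[str, float]:
    """Empirical type-I error of the size-weighted uniformity test under a
    uniform multinomial null."""
    genome = default_toy_genome() if genome is None else genome
    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    p = lengths / lengths.sum()
    draws = rng.multinomial(n_counts, p, size=n_reps)
    rejections = 0
    for row in draws:
        summary = pd.DataFrame({"chrom": genome.names, "length": lengths,
                                "n_bins": lengths // 10,
                                "total_signal": row.astype(float),
                                "mean_signal": row / (lengths / 10)})
        if weighted_chisq_uniformity(summary).p_value < alpha:
            rejections += 1
    return {"n_reps": n_reps, "alpha": alpha,
            "type1_rate": rejections / n_reps}


def _enrichment_table(rng: np.random.Generator, genome: GenomeModel,
                      n_universe: int, n_deg: int, x_share: float,
                      x_deg_multiplier: float) -> pd.DataFrame:
    """Universe with chrX holding ``x_share`` of genes; DEG drawn so the
    expected chrX share of DEG is ``x_deg_multiplier * x_share`` (1 = null)."""
    p_chrom = np.where(np.array(genome.names) == genome.x_name,
                       x_share, (1 - x_share) / (len(genome.names) - 1))
    chroms = rng.choice(genome.names, size=n_universe, p=p_chrom)
    m, s = x_deg_multiplier, x_share
    weight = m * (1 - s) / (1 - m * s) if m * s < 1 else np.inf
    w = np.where(chroms == genome.x_name, weight, 1.0)
    deg_idx = rng.choice(n_universe, size=n_deg, replace=False, p=w / w.sum())
    up = np.zeros(n_universe, dtype=bool)
    up[deg_idx] = True
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n_universe)],
        "chrom": chroms, "baseMean": 100.0, "baseMeanA": 100.0, "baseMeanB": 100.0,
        "log2FoldChange": np.where(up, 2.0, 0.0),
        "padj": np.where(up, 1e-4, 0.9)})


def enrichment_calibration(n_sims: int = 200, n_deg: int = 500,
                           n_universe: int = 3000, seed: int = 0,
                           x_share: float = 0.2, x_deg_multiplier: float = 1.0,
                           genome: GenomeModel | None = None) -> dict[str, float]:
    """False-flag rate (null) or chrX detection power (alternative) of the
    dual-criteria chromosome-enrichment rule."""
    genome = default_toy_genome() if genome is None else genome
    rng = np.random.default_rng(seed)
    any_flag, x_flag = 0, 0
    for _ in range(n_sims):
        table = _enrichment_table(rng, genome, n_universe, n_deg, x_share,
                                  x_deg_multiplier)
        call = call_deg(table)
        out = chromosome_enrichment(call, table, genome, "up")
        if out["flagged"].any():
            any_flag += 1
        if out.set_index("chrom").loc[genome.x_name, "flagged"]:
            x_flag += 1
    return {"n_sims": n_sims, "x_deg_multiplier": x_deg_multiplier,
            "frac_any_flag": any_flag / n_sims,
            "frac_x_flag": x_flag / n_sims}
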