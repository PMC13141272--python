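#!/usr/bin/env python
"""Spike-in normalisation of the synthetic ChIP-seq panel, with the
ground-truth recovery experiment.

Derives per-sample scaling factors from the spike-in counts, normalises all
tracks, and runs the planted-depletion recovery study: spike-in scaling
recovers a known global signal loss that plain per-sample CPM cannot see.

Writes results/scaling_factors.tsv, normalised bedGraphs, and
results/spike_recovery.tsv.
"""

from pathlib import Path

import pandas as pd

import k4gauge as kg
import k4gauge.io as kio
from k4gauge import experiments as ex
from k4gauge.simulate import MARKS

ROOT = Path(__file__).resolve().parents[1] / "results"
FIX = ROOT / "fixtures"


def main(seed: int = 1) -> None:
    genome = kio.read_chrom_sizes(FIX / "genome.chrom.sizes")
    spike = kio.read_table(FIX / "spike_counts.tsv")
    factors = kg.compute_scaling_factors(spike, group_by="mark")
    kio.write_table(factors, ROOT / "scaling_factors.tsv")
    print("scaling factors (per mark, reference sample = 1):")
    print(factors.to_string(index=False))

    outdir = ROOT / "normalised_tracks"
    outdir.mkdir(parents=True, exist_ok=True)
    for mark in MARKS:
        sub = spike[spike["mark"] == mark]
        tracks = {row["sample_id"]: kio.read_bedgraph(
            FIX / f"coverage_{row['genotype']}_{mark}.bedgraph", genome, 10)
            for _, row in sub.iterrows()}
        norm = kg.normalise_experiment(tracks, sub, seed=seed)
        for sample, track in norm.items():
            kio.write_bedgraph(track, outdir / f"{sample}.norm.bedgraph")
    print(f"normalised {3 * len(MARKS)} tracks -> {outdir}")

    rows = []
    for d in (0.1, 0.5):
        out = ex.spike_recovery(d, n_seeds=20, seed0=seed)
        rows.append(out)
        print(f"planted depletion {d}: spike-normalised estimate "
              f"{out['recovered_mean']:.3f}, plain-CPM estimate "
              f"{out['naive_mean']:.3f}")
    kio.write_table(pd.DataFrame(rows), ROOT / "spike_recovery.tsv")


if __name__ == "__main__":
    main()
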