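#!/usr/bin/env python
"""Generate the synthetic study: genome, features, coverage, peaks, spike-in
counts and DEG tables for a wild type, a wdr-5-like and an rbbp-5-like
genotype (plus the derived double mutant).

Writes everything under results/fixtures/ for the downstream drivers.
"""

from pathlib import Path

import k4gauge as kg
from k4gauge.simulate import SimConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed)
    manifest = kg.write_fixtures(OUT, cfg, n_tss=200, n_enh=100)
    print(f"wrote {len(manifest)} fixture files to {OUT}")
    for key, path in sorted(manifest.items()):
        print(f"  {key}: {path.name}")


if __name__ == "__main__":
    main()
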