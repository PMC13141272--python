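"""Chromosome-level coverage statistics.

Used to check that input (non-IP) chromatin coverage is uniform across
chromosomes: per-chromosome means, log2(observed/expected) coverage shares,
a chromosome-size-weighted chi-square goodness-of-fit test, and the log2
ratio of chromosome-X signal to the autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel
from .tracks import CoverageTrack


@dataclass
class UniformityResult:
    log2_obs_exp: pd.Series     # per chromosome
    chisq_stat: float
    df: int
    p_value: float
    x_autosome_log2: float


def per_chrom_summary(track: CoverageTrack, genome: GenomeModel) -> pd.DataFrame:
    """Per-chromosome bin count, total and mean signal (plus genome totals in attrs)."""
    track.validate_against(genome)
    rows = []
    for name, length in genome.chromosomes:
        v = np.asarray(track.values[name], dtype=float)
        rows.append({"chrom": name, "length": length, "n_bins": len(v),
                     "total_signal": float(v.sum()),
                     "mean_signal": float(v.mean()) if len(v) else 0.0})
    out = pd.DataFrame(rows)
    out.attrs["genome_total"] = float(out["total_signal"].sum())
    out.attrs["x_name"] = genome.x_name
    return out


def log2_obs_exp(summary: pd.DataFrame) -> pd.Series:
    """log2 of (signal share / length share) per chromosome.

    Chromosomes with zero signal get -inf, flagged via the series' attrs.
    """
    total = summary["total_signal"].sum()
    if total <= 0:
        raise ValueError("track has zero total signal")
    observed = summary["total_signal"] / total
    expected = summary["length"] / summary["length"].sum()
    with np.errstate(divide="ignore"):
        values = np.log2(observed / expected)
    out = pd.Series(values.to_numpy(), index=summary["chrom"], name="log2_obs_exp")
    out.attrs["zero_chromosomes"] = summary.loc[observed == 0, "chrom"].tolist()
    return out


def weighted_chisq_uniformity(summary: pd.DataFrame, value_scale: float = 1.0
                              ) -> UniformityResult:
    """Chromosome-size-weighted goodness-of-fit test for coverage uniformity.

    Expected counts are proportional to chromosome length.  ``value_scale``
    converts real-valued coverage totals to effective read counts (totals are
    divided by it) when the track is not on the raw-count scale; the test's
    Poisson/multinomial assumption only holds on a counts scale.
    """
    if len(summary) < 2:
        raise ValueError("need at least 2 chromosomes")
    observed = summary["total_signal"].to_numpy(dtype=float) / value_scale
    if observed.sum() <= 0:
        raise ValueError("zero grand total")
    if np.any(observed < 0):
        raise ValueError("negative totals")
    expected = observed.sum() * summary["length"].to_numpy(dtype=float) \
        / summary["length"].sum()
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = len(summary) - 1
    p = float(stats.chi2.sf(stat, df))
    x_name = summary.attrs.get("x_name", "chrX")
    x_log2 = x_autosome_log2(summary) if x_name in set(summary["chrom"]) else np.nan
    return UniformityResult(
        log2_obs_exp=log2_obs_exp(summary),
        chisq_stat=stat, df=df, p_value=max(p, np.finfo(float).tiny),
        x_autosome_log2=x_log2,
    )


def x_autosome_log2(summary: pd.DataFrame, x_name: str | None = None) -> float:
    """log2( mean signal on chrX / length-weighted mean signal on autosomes )."""
    x_name = summary.attrs.get("x_name", "chrX") if x_name is None else x_name
    if x_name not in set(summary["chrom"]):
        raise ValueError(f"{x_name!r} not in summary")
    x_rows = summary["chrom"] == x_name
    auto = summary.loc[~x_rows]
    auto_total = auto["total_signal"].sum()
    auto_bins = auto["n_bins"].sum()
    if auto_total <= 0:
        raise ValueError("zero autosome signal")
    x_mean = float(summary.loc[x_rows, "mean_signal"].iloc[0])
    auto_mean = auto_total / auto_bins
    return float(np.log2(x_mean / auto_mean))
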