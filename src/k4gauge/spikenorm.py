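"""Spike-in scaling factors, downsampling normalisation and CPM coverage.

Foreign (spike-in) chromatin is added at a fixed share of input chromatin
before immunoprecipitation, so the number of foreign reads per library
measures the per-cell IP yield: a sample whose target mark is globally
depleted sequences proportionally *more* foreign reads.  Normalising all
samples to equal foreign-read counts therefore preserves genuine global
differences that composition-based scalings (plain CPM) erase.

The contract implemented here:

1. Within each mark (antibody) group, every sample is scaled *down* to the
   sample with the fewest spike reads: ``factor = min(spike) / spike``.
2. Scaling is applied by binomial thinning of the integer counts
   (downsampling), which preserves count statistics.
3. Tracks are then put on a common counts-per-million scale.  The CPM
   denominator is shared across the group (the reference sample's
   downsampled total): a per-sample denominator would cancel the spike
   factor exactly and reduce the procedure to plain CPM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import stream
from .tracks import CoverageTrack

SPIKE_COLUMNS = ["sample_id", "target_reads", "spike_reads"]


def _validate_spike_table(table: pd.DataFrame) -> None:
    missing = [c for c in SPIKE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spike table missing columns {missing}")
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids {dupes}")
    if (table[["target_reads", "spike_reads"]] < 0).any().any():
        raise ValueError("read counts must be non-negative")


def compute_scaling_factors(table: pd.DataFrame, group_by: str | None = "mark") -> pd.DataFrame:
    """Per-sample downsampling factors: min(spike reads in group) / spike reads.

    The sample with the fewest spike reads in each group is the reference
    (factor 1); all other factors are in (0, 1].  Factors are computed within
    each antibody (mark) group because IP efficiency is antibody-specific.
    """
    _validate_spike_table(table)
    zeros = table.loc[table["spike_reads"] == 0, "sample_id"].tolist()
    if zeros:
        raise ValueError(f"zero spike reads for sample(s) {zeros}")
    out = table.copy()
    if group_by is not None and group_by in table.columns:
        ref = table.groupby(group_by)["spike_reads"].transform("min")
    else:
        ref = table["spike_reads"].min()
    out["factor"] = ref / out["spike_reads"]
    cols = ["sample_id", "factor"] + ([group_by] if group_by in out.columns else [])
    return out[cols]


def downsample_counts(values, factor: float, seed: int):
    """Binomially thin integer counts with probability ``factor``.

    Accepts a count vector or an integer-valued :class:`CoverageTrack` and
    returns the same type.  Expected total = factor x original total.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"downsampling factor must be in (0, 1], got {factor}")
    rng = stream(seed, "downsample")
    if isinstance(values, CoverageTrack):
        if not values.is_integer():
            raise ValueError("downsampling requires integer counts")
        if factor == 1.0:
            return values.copy_with({c: v.copy() for c, v in values.values.items()})
        thinned = {c: rng.binomial(np.asarray(v, dtype=np.int64), factor)
                   for c, v in values.values.items()}
        return values.copy_with(thinned)
    arr = np.asarray(values)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("downsampling requires integer counts")
        arr = np.round(arr).astype(np.int64)
    if factor == 1.0:
        return arr.copy()
    return rng.binomial(arr, factor)


def cpm_normalise(track: CoverageTrack, denominator: float | None = None) -> CoverageTrack:
    """Counts-per-million scaling: bin value x 1e6 / total counts.

    ``denominator`` overrides the track's own total; the spike-normalisation
    pipeline passes a group-shared denominator so cross-sample ratios are
    preserved.
    """
    total = track.total() if denominator is None else float(denominator)
    if total <= 0:
        raise ValueError("cannot CPM-normalise a track with zero total counts")
    values = {c: np.asarray(v, dtype=float) * 1e6 / total
              for c, v in track.values.items()}
    return track.copy_with(values, normalisation="cpm")


def normalise_experiment(tracks: dict[str, CoverageTrack], spike_table: pd.DataFrame,
                         seed: int, factors: pd.DataFrame | None = None,
                         group_by: str | None = "mark") -> dict[str, CoverageTrack]:
    """Spike-normalise a set of per-sample raw-count tracks.

    Each sample is binomially downsampled by its spike factor, then scaled by
    one counts-per-million constant shared within its group (1e6 over the
    reference sample's downsampled total).  Output tracks carry the
    ``spike_normalised`` tag.
    """
    _validate_spike_table(spike_table)
    missing = [s for s in spike_table["sample_id"] if s not in tracks]
    if missing:
        raise ValueError(f"missing track for sample(s) {missing}")
    if factors is None:
        factors = compute_scaling_factors(spike_table, group_by=group_by)
    if group_by is not None and group_by in factors.columns:
        group_max = factors.groupby(group_by)["factor"].transform("max")
    else:
        group_max = pd.Series(factors["factor"].max(), index=factors.index)
    if not np.allclose(group_max, 1.0):
        raise ValueError("factor table violates the reference convention "
                         "(every group needs a sample with factor 1)")

    fmap = dict(zip(factors["sample_id"], factors["factor"]))
    downsampled = {}
    for i, sample in enumerate(spike_table["sample_id"]):
        downsampled[sample] = downsample_counts(tracks[sample], fmap[sample],
                                                seed=seed + i)

    # one CPM denominator per group, taken from that group's reference sample
    if group_by is not None and group_by in factors.columns:
        groups = dict(zip(factors["sample_id"], factors[group_by]))
    else:
        groups = {s: "all" for s in factors["sample_id"]}
    denom: dict[str, float] = {}
    for sample, factor in fmap.items():
        if np.isclose(factor, 1.0):
            denom.setdefault(groups[sample], downsampled[sample].total())

    out = {}
    for sample, track in downsampled.items():
        scaled = cpm_normalise(track, denominator=denom[groups[sample]])
        scaled.normalisation = "spike_normalised"
        out[sample] = scaled
    return out
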