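"""Signal matrices around anchors, High/Low clustering and aggregate profiles.

A signal matrix holds, per region, the mean coverage in fixed-width bins
spanning ``+/- flank`` around an anchor (a TSS, an enhancer midpoint or a
peak summit).  The matrix bin grid is anchored at the region, not at the
genome grid: where a matrix bin straddles track bins, the overlap-weighted
mean of the track values is used.  Rows of minus-strand anchors are reversed
so downstream of transcription is always to the right.  Bins extending past
a chromosome end are missing (NaN), never zero-filled.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .tracks import CoverageTrack

ANCHOR_KINDS = ("TSS", "enhancer_midpoint", "peak_summit")


@dataclass
class SignalMatrix:
    values: np.ndarray          # regions x bins, NaN = missing
    region_ids: list[str]
    anchor_kind: str
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), 2 * self.flank // self.bin_size):
            raise ValueError("matrix shape inconsistent with flank/bin_size/regions")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def bin_centers(self) -> np.ndarray:
        """Offsets of bin centers relative to the anchor (bp)."""
        edges = np.arange(-self.flank, self.flank + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2

    def save(self, path: str) -> None:
        header = json.dumps({"anchor_kind": self.anchor_kind, "flank": self.flank,
                             "bin_size": self.bin_size})
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write(f"#{header}\n")
            pd.DataFrame(self.values, index=self.region_ids).to_csv(fh, sep="\t",
                                                                    header=False)

    @classmethod
    def load(cls, path: str) -> "SignalMatrix":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            meta = json.loads(fh.readline().lstrip("#"))
            df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        return cls(values=df.to_numpy(), region_ids=[str(i) for i in df.index],
                   **meta)


@dataclass
class ClusterAssignment:
    labels: dict[str, str]      # region id -> "me3_High" | "me3_Low"
    degenerate: bool = False    # all rows identical: no real second cluster
    meta: dict = field(default_factory=dict)

    def ids(self, label: str) -> list[str]:
        return [r for r, l in self.labels.items() if l == label]


def extract_matrix(track: CoverageTrack, anchors: pd.DataFrame, flank: int,
                   bin_size: int, anchor_kind: str = "TSS") -> SignalMatrix:
    """Per-region binned mean signal over ``[anchor - flank, anchor + flank)``.

    ``anchors`` is a BED6-like frame; the anchor point is the interval
    midpoint (for single-base anchors, the base itself).  Minus-strand rows
    are reversed.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    unknown = sorted(set(anchors["chrom"]) - set(track.values))
    if unknown:
        ids = anchors.loc[anchors["chrom"].isin(unknown), "name"].tolist()
        raise ValueError(f"anchors on unknown chromosome(s) {unknown}: {ids}")

    n_cols = 2 * flank // bin_size
    out = np.full((len(anchors), n_cols), np.nan)
    tb = track.bin_size

    # prefix sums of per-base signal per chromosome: S[x] = integral over [0, x)
    prefix = {}
    for chrom, v in track.values.items():
        widths = np.full(len(v), tb, dtype=float)
        cum = np.concatenate(([0.0], np.cumsum(np.asarray(v, dtype=float) * widths)))
        prefix[chrom] = cum

    for r, (_, row) in enumerate(anchors.iterrows()):
        chrom = row["chrom"]
        anchor = (int(row["start"]) + int(row["end"])) // 2
        cum = prefix[chrom]
        chrom_len_binned = (len(cum) - 1) * tb
        edges = anchor - flank + np.arange(n_cols + 1) * bin_size
        valid = (edges[:-1] >= 0) & (edges[1:] <= chrom_len_binned)
        lo = np.clip(edges[:-1], 0, chrom_len_binned)
        hi = np.clip(edges[1:], 0, chrom_len_binned)

        def integral(x):
            i = np.asarray(x) // tb
            frac = np.asarray(x) - i * tb
            base = cum[np.minimum(i, len(cum) - 1).astype(int)]
            val = np.where(i < len(cum) - 1,
                           np.diff(cum)[np.minimum(i, len(cum) - 2).astype(int)] / tb,
                           0.0)
            return base + frac * val

        sums = integral(hi) - integral(lo)
        means = np.where(valid, sums / bin_size, np.nan)
        if str(row.get("strand", "+")) == "-":
            means = means[::-1]
        out[r] = means

    ids = [str(n) for n in anchors["name"]] if "name" in anchors.columns \
        else [str(i) for i in range(len(anchors))]
    return SignalMatrix(values=out, region_ids=ids, anchor_kind=anchor_kind,
                        flank=flank, bin_size=bin_size)


def kmeans_high_low(matrix: SignalMatrix, seed: int, n_restarts: int = 10,
                    on_row_means: bool = False) -> ClusterAssignment:
    """k = 2 clustering of regions into 'me3_High' and 'me3_Low'.

    Operates on the raw binned row vectors (the High/Low split is by signal
    level, so rows are not normalised); ``on_row_means`` collapses each row
    to its mean first.  Missing cells are imputed with the row mean.  The
    cluster with the larger mean row-sum is High.  Identical rows yield a
    single effective cluster: everything is labelled Low with a warning.
    """
    if matrix.n_regions < 2:
        raise ValueError("need at least 2 regions to cluster")
    x = matrix.values.copy()
    row_mean = np.nanmean(x, axis=1, keepdims=True)
    row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
    x = np.where(np.isnan(x), row_mean, x)
    if on_row_means:
        x = x.mean(axis=1, keepdims=True)

    if np.allclose(x, x[0]):
        warnings.warn("all rows identical: single effective cluster, all me3_Low")
        return ClusterAssignment({r: "me3_Low" for r in matrix.region_ids},
                                 degenerate=True)

    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(x)
    sums = x.sum(axis=1)
    high = max((0, 1), key=lambda k: sums[assign == k].mean())
    labels = {rid: ("me3_High" if a == high else "me3_Low")
              for rid, a in zip(matrix.region_ids, assign)}
    return ClusterAssignment(labels, meta={"inertia": float(km.inertia_)})


def aggregate_profile(matrix: SignalMatrix,
                      group: dict[str, str] | ClusterAssignment | None = None
                      ) -> pd.DataFrame:
    """Column-wise mean and sd per group of regions, missing-aware.

    Returns a long frame (group, offset, mean, sd, n_regions); with no
    grouping, a single group 'all'.
    """
    if isinstance(group, ClusterAssignment):
        group = group.labels
    if group is None:
        group = {r: "all" for r in matrix.region_ids}
    missing = set(matrix.region_ids) - set(group)
    if missing:
        raise ValueError(f"regions without a group: {sorted(missing)[:5]} ...")

    centers = matrix.bin_centers()
    frames = []
    for name in sorted(set(group.values())):
        rows = [i for i, rid in enumerate(matrix.region_ids) if group[rid] == name]
        if rows:
            sub = matrix.values[rows]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                mean = np.nanmean(sub, axis=0)
                sd = np.nanstd(sub, axis=0)
        else:
            mean = np.full(len(centers), np.nan)
            sd = np.full(len(centers), np.nan)
        frames.append(pd.DataFrame({"group": name, "offset": centers,
                                    "mean": mean, "sd": sd,
                                    "n_regions": len(rows)}))
    return pd.concat(frames, ignore_index=True)
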