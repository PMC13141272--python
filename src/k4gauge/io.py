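"""Readers and writers for the plain-text interchange formats.

All coordinates are 0-based half-open (BED convention). bedGraph is the
coverage interchange format: the writer run-length-merges adjacent equal-value
bins, the reader expands intervals back onto the fixed bin grid, so a
write/read round trip reproduces the track exactly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genome import GenomeModel, build_genome
from .tracks import CoverageTrack, n_bins

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BROADPEAK_COLUMNS = BED6_COLUMNS + ["signalValue", "pValue", "qValue"]


# -- chrom.sizes ------------------------------------------------------------

def write_chrom_sizes(genome: GenomeModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | os.PathLike, x_name: str = "chrX") -> GenomeModel:
    spec = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            spec.append((name, int(length)))
    return build_genome(spec, x_name=x_name)


# -- BED6 -------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                     dtype={"chrom": str, "name": str, "strand": str})
    if len(df) == 0:
        return pd.DataFrame(columns=BED6_COLUMNS)
    return df


# -- bedGraph ---------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    frames = []
    for chrom, values in track.values.items():
        v = np.asarray(values)
        if len(v) == 0:
            continue
        # run-length encode equal adjacent bins
        change = np.flatnonzero(v[1:] != v[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        bs = track.bin_size
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts * bs,
                                    "end": ends * bs, "value": v[starts]}))
    out = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["chrom", "start", "end", "value"])
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | os.PathLike, genome: GenomeModel, bin_size: int,
                  normalisation: str = "raw") -> CoverageTrack:
    values = {name: np.zeros(n_bins(genome.length(name), bin_size))
              for name in genome.names}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, val = line.split()[:4]
            if chrom not in values:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            s, e = int(start), int(end)
            if s % bin_size or (e % bin_size and e != genome.length(chrom)):
                raise ValueError(f"interval {chrom}:{s}-{e} not aligned to {bin_size} bp bins")
            values[chrom][s // bin_size: -(-e // bin_size)] = float(val)
    out = {}
    for chrom, v in values.items():
        rounded = np.round(v)
        out[chrom] = rounded.astype(np.int64) if np.array_equal(rounded, v) else v
    return CoverageTrack(bin_size=bin_size, values=out, normalisation=normalisation)


# -- broadPeak --------------------------------------------------------------

def write_broadpeak(peaks: pd.DataFrame, path: str | os.PathLike,
                    extra_columns: list[str] | None = None) -> None:
    cols = BROADPEAK_COLUMNS + (extra_columns or [])
    peaks.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_broadpeak(path: str | os.PathLike, mark: str | None = None,
                   genotype: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(9),
                     names=BROADPEAK_COLUMNS, dtype={"chrom": str, "name": str, "strand": str})
    if mark is not None:
        df["mark"] = mark
    if genotype is not None:
        df["genotype"] = genotype
    return df


# -- TSV tables -------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
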