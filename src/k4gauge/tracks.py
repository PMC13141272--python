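"""Binned coverage tracks.

A :class:`CoverageTrack` is a fixed-width binned signal per chromosome, the
in-memory form of a bedGraph/bigWig: bin ``j`` of a chromosome covers
``[j*bin_size, (j+1)*bin_size)`` (the last bin may be truncated by the
chromosome end, but still stores one value). Values are non-negative; the
``normalisation`` tag records which scaling has been applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel

VALID_TAGS = ("raw", "cpm", "spike_normalised")


def n_bins(chrom_length: int, bin_size: int) -> int:
    return -(-chrom_length // bin_size)


@dataclass
class CoverageTrack:
    bin_size: int
    values: dict[str, np.ndarray]
    normalisation: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.normalisation not in VALID_TAGS:
            raise ValueError(f"unknown normalisation tag {self.normalisation!r}")
        self.values = {c: np.asarray(v) for c, v in self.values.items()}
        for chrom, v in self.values.items():
            if v.ndim != 1:
                raise ValueError(f"values for {chrom} must be a 1-D vector")
            if np.any(v < 0):
                raise ValueError(f"negative coverage on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def is_integer(self) -> bool:
        return all(np.issubdtype(v.dtype, np.integer) or np.allclose(v, np.round(v))
                   for v in self.values.values())

    def copy_with(self, values: dict[str, np.ndarray], normalisation: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            bin_size=self.bin_size,
            values=values,
            normalisation=self.normalisation if normalisation is None else normalisation,
            meta=dict(self.meta),
        )

    def validate_against(self, genome: GenomeModel) -> None:
        """Check that every genome chromosome is present with the right bin count."""
        for name in genome.names:
            if name not in self.values:
                raise ValueError(f"track missing chromosome {name}")
            expect = n_bins(genome.length(name), self.bin_size)
            got = len(self.values[name])
            if got != expect:
                raise ValueError(
                    f"{name}: expected {expect} bins for length {genome.length(name)}"
                    f" at bin size {self.bin_size}, got {got}"
                )
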