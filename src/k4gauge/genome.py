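"""Genome model: an ordered chromosome set with an X chromosome designation.

The worm genome has five autosomes (I-V) and chromosome X; several analyses
(X/autosome ratios, X-specific simulation effects) need that partition, so the
model carries the X name explicitly rather than inferring it.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths (bp) and the name of chromosome X."""

    chromosomes: tuple[tuple[str, int], ...]
    x_name: str
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if not names:
            raise ValueError("genome must have at least one chromosome")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.x_name not in names:
            raise ValueError(f"x_name {self.x_name!r} not among chromosomes")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def autosomes(self) -> list[str]:
        return [n for n in self.names if n != self.x_name]

    def length(self, name: str) -> int:
        return self._lengths[name]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


def build_genome(spec: list[tuple[str, int]], x_name: str) -> GenomeModel:
    """Validate and build a :class:`GenomeModel` preserving input order."""
    return GenomeModel(chromosomes=tuple((str(n), int(l)) for n, l in spec), x_name=x_name)


def default_toy_genome(chrom_length: int = 1_000_000) -> GenomeModel:
    """Six chromosomes (I-V, X) of equal length; the package's test genome."""
    names = ["chrI", "chrII", "chrIII", "chrIV", "chrV", "chrX"]
    return build_genome([(n, chrom_length) for n in names], x_name="chrX")
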