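"""Genome builds: chromosome names, lengths and autosome flags.

A :class:`GenomeBuild` is the coordinate authority for the whole pipeline:
every reader validates chromosome names against it, CNV filtering restricts
to its autosomes, and genome fractions are computed against its autosomal
length.  A table of the Sscrofa11.1 autosomes (chromosomes 1-18 of the pig
reference assembly) ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["Chromosome", "GenomeBuild", "read_genome_table", "sus_scrofa_11_1"]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    is_autosome: bool

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with an exposed autosomal length."""

    name: str
    chromosomes: tuple[Chromosome, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome build")
        if not any(c.is_autosome for c in self.chromosomes):
            raise ValueError("genome build has no autosomes")
        object.__setattr__(self, "_index", {c.name: c for c in self.chromosomes})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __getitem__(self, chrom: str) -> Chromosome:
        return self._index[chrom]

    @property
    def autosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if c.is_autosome)

    @property
    def autosomal_length(self) -> int:
        return sum(c.length_bp for c in self.autosomes)

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self._index and self._index[chrom].is_autosome

    def chrom_order(self, chrom: str) -> int:
        """Rank of a chromosome in build order (for deterministic sorting)."""
        for i, c in enumerate(self.chromosomes):
            if c.name == chrom:
                return i
        raise KeyError(chrom)

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "GenomeBuild":
        chroms = tuple(
            Chromosome(str(r.chrom), int(r.length), bool(r.is_autosome))
            for r in df.itertuples()
        )
        return cls(name, chroms)


def read_genome_table(path: str | Path, name: str | None = None) -> GenomeBuild:
    """Read a genome table TSV with columns ``chrom``, ``length``, ``is_autosome``.

    ``is_autosome`` accepts 0/1 or true/false (case-insensitive).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "length", "is_autosome"} - set(df.columns)
    if missing:
        raise ValueError(f"genome table {path}: missing columns {sorted(missing)}")
    truthy = {"1", "true", "yes"}
    df["is_autosome"] = (
        df["is_autosome"].astype(str).str.strip().str.lower().isin(truthy)
    )
    return GenomeBuild.from_frame(name or Path(path).stem, df)


def sus_scrofa_11_1() -> GenomeBuild:
    """The 18 autosomes of the pig reference assembly Sscrofa11.1 (Ensembl)."""
    with resources.as_file(
        resources.files("cnvrpipe.data").joinpath("sscrofa11_1_autosomes.tsv")
    ) as p:
        return read_genome_table(p, name="Sscrofa11.1")
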