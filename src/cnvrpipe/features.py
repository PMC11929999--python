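"""Genomic features: gene models with exonic unions, and QTL records."""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import Interval, merge_adjacent

__all__ = ["GeneModel", "QtlRecord"]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exons; the exonic union is precomputed on build.

    Exon intervals are 1-based inclusive and must share the gene's
    chromosome.  ``exonic_union`` holds the merged (double-count-free)
    exonic intervals; ``exonic_length`` is their total base count.
    """

    gene_id: str
    chrom: str
    exons: tuple[Interval, ...]
    symbol: str | None = None
    strand: str = "unknown"  # '+', '-', or 'unknown'
    body: Interval | None = None  # gene-feature coordinates when known

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exon list is empty")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"gene {self.gene_id}: exon on another chromosome")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.body is not None and self.body.chrom != self.chrom:
            raise ValueError(f"gene {self.gene_id}: body on another chromosome")

    @property
    def exonic_union(self) -> tuple[Interval, ...]:
        return tuple(merge_adjacent(self.exons))

    @property
    def exonic_length(self) -> int:
        return sum(iv.length for iv in self.exonic_union)

    @property
    def span(self) -> Interval:
        """Gene body: the gene feature's coordinates, or the exon hull."""
        if self.body is not None:
            return self.body
        return Interval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )


@dataclass(frozen=True)
class QtlRecord:
    """One QTL interval associated with a named trait."""

    qtl_id: str
    trait_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"QTL {self.qtl_id}: end < start")
        if not self.trait_name:
            raise ValueError(f"QTL {self.qtl_id}: empty trait name")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)
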