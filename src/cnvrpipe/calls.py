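"""Per-caller CNV calls: filtering, typing, and pooled union loci.

A :class:`CnvCall` is one caller's deletion or duplication in one sample.
Calls from all four callers are pooled into a union dataset; duplicates are
removed by clustering same-type calls at 50% reciprocal overlap, yielding
:class:`UnionLocus` objects that drive the binary presence/absence matrix
and the universal extreme-copy-number screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .features import GeneModel
from .genome import GenomeBuild
from .intervals import (
    Interval,
    cluster_reciprocal,
    cluster_span,
    merge_adjacent,
    overlap_length,
)

LOSS = "loss"
GAIN = "gain"

__all__ = [
    "LOSS",
    "GAIN",
    "CnvCall",
    "FilterConfig",
    "UnionLocus",
    "classify_call_type",
    "filter_calls",
    "build_union_loci",
    "extract_extreme_cn_shared",
    "exon_overlap_select",
]


def classify_call_type(copy_number: int | None = None, svtype: str | None = None) -> str:
    """loss/gain from a copy number (< 2 / > 2) or an SVTYPE (DEL/DUP).

    A copy number of exactly 2 is the diploid state and not a CNV.
    """
    if copy_number is not None:
        if copy_number == 2:
            raise ValueError("copy number 2 is diploid: not a CNV")
        return LOSS if copy_number < 2 else GAIN
    if svtype is not None:
        if svtype == "DEL":
            return LOSS
        if svtype == "DUP":
            return GAIN
        raise ValueError(f"unsupported SVTYPE {svtype!r}")
    raise ValueError("need a copy number or an SVTYPE")


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV call in one sample (1-based inclusive interval)."""

    sample_id: str
    tool: str
    chrom: str
    start: int
    end: int
    cnv_type: str  # loss | gain
    copy_number: int | None = None
    genotype: str = "unknown"  # het | hom | unknown

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"{self.sample_id}/{self.tool} {self.chrom}:{self.start}-{self.end}: "
                "end < start"
            )
        if self.cnv_type not in (LOSS, GAIN):
            raise ValueError(f"bad cnv_type {self.cnv_type!r}")
        if self.genotype not in ("het", "hom", "unknown"):
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.copy_number is not None:
            if self.copy_number < 0:
                raise ValueError("negative copy number")
            if classify_call_type(copy_number=self.copy_number) != self.cnv_type:
                raise ValueError(
                    f"cnv_type {self.cnv_type} inconsistent with CN={self.copy_number}"
                )

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FilterConfig:
    """Size and chromosome filters applied to every raw call set.

    Defaults follow the study conventions: minimum variant size 50 bp,
    calls larger than 5 Mb excluded, autosomes only.
    """

    min_len_bp: int = 50
    max_len_bp: int = 5_000_000
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_len_bp < self.max_len_bp:
            raise ValueError("need 0 < min_len_bp < max_len_bp")


def filter_calls(
    calls: Iterable[CnvCall],
    build: GenomeBuild,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[CnvCall], dict[str, int]]:
    """Apply size/autosome filters; return (kept calls, removal counts).

    Removal counts are keyed ``too_short``, ``too_long``, ``non_autosomal``
    and sum to the number of removed calls (each call is charged to the
    first reason that fires, in that order).
    """
    kept: list[CnvCall] = []
    removed = {"too_short": 0, "too_long": 0, "non_autosomal": 0}
    for c in calls:
        if c.length < cfg.min_len_bp:
            removed["too_short"] += 1
        elif c.length > cfg.max_len_bp:
            removed["too_long"] += 1
        elif cfg.autosomes_only and not build.is_autosome(c.chrom):
            removed["non_autosomal"] += 1
        else:
            kept.append(c)
    return kept, removed


@dataclass(frozen=True)
class UnionLocus:
    """One deduplicated locus of the pooled cross-tool call set."""

    span: Interval
    cnv_type: str
    members: tuple[CnvCall, ...] = field(repr=False)

    @property
    def locus_id(self) -> str:
        return f"{self.span.chrom}:{self.span.start}-{self.span.end}:{self.cnv_type}"

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset(m.sample_id for m in self.members)

    @property
    def tools(self) -> frozenset[str]:
        return frozenset(m.tool for m in self.members)


def build_union_loci(
    calls: Sequence[CnvCall], ro_threshold: float = 0.5
) -> list[UnionLocus]:
    """Pool calls and deduplicate per type at the reciprocal-overlap threshold.

    Loss and gain calls never co-cluster; loci of different types may overlap
    spatially.  Every input call belongs to exactly one locus.  Loci are
    returned sorted by (chrom, start, end, type).
    """
    loci: list[UnionLocus] = []
    for cnv_type in (LOSS, GAIN):
        typed = [c for c in calls if c.cnv_type == cnv_type]
        if not typed:
            continue
        ivs = [c.interval for c in typed]
        for cluster in cluster_reciprocal(ivs, ro_threshold):
            span = cluster_span(ivs, cluster)
            loci.append(
                UnionLocus(span, cnv_type, tuple(typed[i] for i in cluster))
            )
    loci.sort(key=lambda l: (l.span.chrom, l.span.start, l.span.end, l.cnv_type))
    return loci


def extract_extreme_cn_shared(
    calls: Sequence[CnvCall],
    samples: Sequence[str],
    ro_threshold: float = 0.5,
) -> list[UnionLocus]:
    """Universal extreme-copy-number loci: CN 0 or CN >= 4 in every sample.

    Only calls with copy number 0 (homozygous deletion) or >= 4 (homozygous
    duplication) enter clustering; a locus is retained only if at least one
    member call comes from EVERY sample in ``samples``.
    """
    if not samples:
        raise ValueError("empty sample list")
    extreme = [
        c
        for c in calls
        if c.copy_number is not None and (c.copy_number == 0 or c.copy_number >= 4)
    ]
    loci = build_union_loci(extreme, ro_threshold)
    want = set(samples)
    return [l for l in loci if want <= l.sample_ids]


def exon_overlap_select(
    loci: Sequence[UnionLocus],
    genes: Sequence[GeneModel],
    min_frac: float = 0.5,
) -> list[tuple[UnionLocus, list[GeneModel], list[Interval]]]:
    """Retain loci with >= ``min_frac`` of their bases inside exons.

    The overlap fraction is computed against the union of exonic bases over
    all genes, relative to the locus length.  For each retained locus, all
    genes whose exons overlap it by >= 1 bp are reported (deduplicated, in
    input order) together with the overlapping exon intervals.
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out: list[tuple[UnionLocus, list[GeneModel], list[Interval]]] = []
    for locus in loci:
        hits: list[GeneModel] = []
        hit_exons: list[Interval] = []
        exonic_pieces: list[Interval] = []
        for g in genes_by_chrom.get(locus.span.chrom, []):
            gene_hit = False
            for ex in g.exons:
                if overlap_length(ex, locus.span) > 0:
                    gene_hit = True
                    if ex not in hit_exons:
                        hit_exons.append(ex)
            if gene_hit:
                hits.append(g)
                exonic_pieces.extend(g.exonic_union)
        if not hits:
            continue
        covered = sum(
            overlap_length(piece, locus.span)
            for piece in merge_adjacent(exonic_pieces)
        )
        if covered / locus.span.length >= min_frac:
            out.append((locus, hits, hit_exons))
    return out
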