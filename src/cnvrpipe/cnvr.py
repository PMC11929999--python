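"""CNVR assembly: per-tool regions, multi-tool consensus, sharing rules.

The CNVR (copy-number-variation region) is the population-level unit of the
analysis.  Per tool, calls of the same type merging by >= 1 bp form
candidate regions; low-density sub-segments (supported by fewer than 10% of
the region's contributing calls) are trimmed away, and post-trim loss and
gain regions that overlap are fused into 'both' regions.  Across tools,
same-type regions overlapping by >= 1 bp combine into consensus CNVRs kept
only when >= 2 distinct tools support them.  Sharing rules then select the
all-breed set (>= 2 individuals in every breed) and per-region sets (every
animal of the region); region-exclusive CNVRs have zero base-pair overlap
with any other region's set.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .calls import GAIN, LOSS, CnvCall
from .genome import GenomeBuild
from .intervals import (
    Interval,
    coalesce,
    merge_adjacent,
    overlap_length,
    support_profile,
)
from .samples import SampleSheet

BOTH = "both"

__all__ = [
    "BOTH",
    "Cnvr",
    "CnvrSummary",
    "SharingResult",
    "build_tool_cnvrs",
    "consensus_cnvrs",
    "shared_cnvrs",
    "exclusive_cnvrs",
    "summarize_cnvrs",
]


@dataclass(frozen=True)
class Cnvr:
    """A population-level CNV region with full bookkeeping."""

    span: Interval
    cnvr_type: str  # loss | gain | both
    tools: frozenset[str]
    samples: frozenset[str]
    n_calls: int
    calls: tuple[CnvCall, ...] = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.cnvr_type not in (LOSS, GAIN, BOTH):
            raise ValueError(f"bad cnvr_type {self.cnvr_type!r}")
        if not self.tools:
            raise ValueError("CNVR needs >= 1 supporting tool")
        if self.n_calls < len(self.samples):
            raise ValueError("n_calls cannot be below the number of samples")

    @property
    def length(self) -> int:
        return self.span.length


def _retype(calls: Sequence[CnvCall]) -> str:
    types = {c.cnv_type for c in calls}
    if types == {LOSS}:
        return LOSS
    if types == {GAIN}:
        return GAIN
    return BOTH


def _make_cnvr(span: Interval, calls: Sequence[CnvCall], cnvr_type: str | None = None) -> Cnvr:
    return Cnvr(
        span=span,
        cnvr_type=cnvr_type or _retype(calls),
        tools=frozenset(c.tool for c in calls),
        samples=frozenset(c.sample_id for c in calls),
        n_calls=len(calls),
        calls=tuple(calls),
    )


def _sorted_cnvrs(cnvrs: Iterable[Cnvr]) -> list[Cnvr]:
    return sorted(
        cnvrs, key=lambda r: (r.span.chrom, r.span.start, r.span.end, r.cnvr_type)
    )


def build_tool_cnvrs(
    calls: Sequence[CnvCall], density_min: float = 0.10
) -> list[Cnvr]:
    """Assemble one tool's filtered calls into density-trimmed CNVRs.

    Per type, calls overlapping by >= 1 bp merge into candidate regions.
    Within each candidate, the per-base support profile is computed and
    maximal sub-segments supported by fewer than ``density_min`` of the
    region's contributing calls are removed, splitting the region where an
    interior segment falls below threshold.  Finally, post-trim loss and
    gain regions that overlap by >= 1 bp are fused into 'both' regions.
    """
    if not calls:
        return []
    tools = {c.tool for c in calls}
    if len(tools) != 1:
        raise ValueError(f"build_tool_cnvrs expects one tool, got {sorted(tools)}")

    trimmed: list[tuple[Interval, list[CnvCall]]] = []
    for cnv_type in (LOSS, GAIN):
        typed = [c for c in calls if c.cnv_type == cnv_type]
        if not typed:
            continue
        regions = merge_adjacent([c.interval for c in typed])
        for region in regions:
            contrib = [c for c in typed if overlap_length(c.interval, region) > 0]
            prof = support_profile(region, [c.interval for c in contrib])
            # keep bases supported by >= density_min of contributing calls
            cutoff = density_min * len(contrib)
            kept = [
                Interval(region.chrom, s, e)
                for s, e, sup in prof.segments
                if sup >= cutoff - 1e-12
            ]
            for piece in coalesce(kept) if kept else []:
                piece_calls = [
                    c for c in contrib if overlap_length(c.interval, piece) > 0
                ]
                trimmed.append((piece, piece_calls))

    # fuse overlapping post-trim loss/gain regions into 'both'
    out: list[Cnvr] = []
    by_chrom: dict[str, list[tuple[Interval, list[CnvCall]]]] = {}
    for piece, pcalls in trimmed:
        by_chrom.setdefault(piece.chrom, []).append((piece, pcalls))
    for chrom, pieces in by_chrom.items():
        pieces.sort(key=lambda t: (t[0].start, t[0].end))
        group: list[tuple[Interval, list[CnvCall]]] = []
        group_end = -1
        for piece, pcalls in pieces:
            if group and piece.start <= group_end:
                group.append((piece, pcalls))
                group_end = max(group_end, piece.end)
            else:
                if group:
                    out.append(_fuse_group(group))
                group = [(piece, pcalls)]
                group_end = piece.end
        if group:
            out.append(_fuse_group(group))
    return _sorted_cnvrs(out)


def _fuse_group(group: list[tuple[Interval, list[CnvCall]]]) -> Cnvr:
    span = Interval(
        group[0][0].chrom,
        min(p.start for p, _ in group),
        max(p.end for p, _ in group),
    )
    calls: list[CnvCall] = []
    for _, pcalls in group:
        for c in pcalls:
            if c not in calls:
                calls.append(c)
    return _make_cnvr(span, calls)


def _types_compatible(a: str, b: str) -> bool:
    return a == b or BOTH in (a, b)


def consensus_cnvrs(
    tool_sets: Sequence[Sequence[Cnvr]], min_tools: int = 2
) -> list[Cnvr]:
    """Combine same-type CNVRs across tools; keep >= ``min_tools`` support.

    Regions of the same type from different tools that overlap by >= 1 bp
    are combined transitively (union span and bookkeeping); 'both' regions
    combine with either type.  Combined regions supported by fewer than
    ``min_tools`` distinct tools are discarded.  The fused region is retyped
    from its full contributing call set.
    """
    if len(tool_sets) < min_tools:
        raise ValueError(
            f"need >= {min_tools} tool CNVR sets, got {len(tool_sets)}"
        )
    nodes: list[Cnvr] = [r for ts in tool_sets for r in ts]
    n = len(nodes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(nodes):
        by_chrom.setdefault(r.span.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (nodes[i].span.start, nodes[i].span.end))
        active: list[int] = []
        for i in idxs:
            a = nodes[i]
            still = []
            for j in active:
                b = nodes[j]
                if b.span.end < a.span.start:
                    continue
                still.append(j)
                if _types_compatible(a.cnvr_type, b.cnvr_type):
                    union(i, j)
            still.append(i)
            active = still

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    out: list[Cnvr] = []
    for members in comps.values():
        regs = [nodes[i] for i in members]
        tools = frozenset(t for r in regs for t in r.tools)
        if len(tools) < min_tools:
            continue
        span = Interval(
            regs[0].span.chrom,
            min(r.span.start for r in regs),
            max(r.span.end for r in regs),
        )
        calls: list[CnvCall] = []
        for r in regs:
            for c in r.calls:
                if c not in calls:
                    calls.append(c)
        out.append(_make_cnvr(span, calls))
    return _sorted_cnvrs(out)


@dataclass(frozen=True)
class SharingResult:
    """A shared CNVR selection with its singleton/doubleton side lists."""

    kept: tuple[Cnvr, ...]
    singletons: tuple[Cnvr, ...]
    doubletons: tuple[Cnvr, ...]
    support: Mapping[Interval, frozenset[str]]  # span -> supporting individuals


def _supporting_samples(
    cnvr: Cnvr, calls_by_sample: Mapping[str, list[Interval]]
) -> frozenset[str]:
    sup = set()
    for sample, ivs in calls_by_sample.items():
        for iv in ivs:
            if overlap_length(iv, cnvr.span) > 0:
                sup.add(sample)
                break
    return frozenset(sup)


def shared_cnvrs(
    consensus: Sequence[Cnvr],
    all_calls: Sequence[CnvCall],
    sheet: SampleSheet,
    mode: str = "per_breed_min2",
    region: str | None = None,
    min_per_breed: int = 2,
) -> SharingResult:
    """Apply the breed/region sharing rules to consensus CNVRs.

    An individual "has" a CNVR iff >= 1 of its filtered calls (any tool)
    overlaps the CNVR span by >= 1 bp.

    mode ``per_breed_min2``: keep CNVRs supported by >= ``min_per_breed``
    individuals in EVERY breed of the sheet.  mode ``region_all``: keep
    CNVRs supported by ALL individuals of ``region``.  Singletons and
    doubletons (1 or 2 supporting individuals overall) are reported
    separately and never enter the kept set.
    """
    if mode not in ("per_breed_min2", "region_all"):
        raise ValueError(f"unknown sharing mode {mode!r}")
    if mode == "region_all" and region is None:
        raise ValueError("region_all mode needs a region")
    if mode == "per_breed_min2":
        for breed in sheet.breeds:
            if len(sheet.samples_of_breed(breed)) < min_per_breed:
                raise ValueError(
                    f"breed {breed!r} has fewer than {min_per_breed} sampled "
                    "individuals; the per-breed sharing rule cannot be met"
                )

    calls_by_sample: dict[str, list[Interval]] = {s: [] for s in sheet.samples}
    for c in all_calls:
        if c.sample_id not in calls_by_sample:
            raise ValueError(f"call sample {c.sample_id!r} absent from sheet")
        calls_by_sample[c.sample_id].append(c.interval)

    kept: list[Cnvr] = []
    singles: list[Cnvr] = []
    doubles: list[Cnvr] = []
    support: dict[Interval, frozenset[str]] = {}
    for cnvr in consensus:
        sup = _supporting_samples(cnvr, calls_by_sample)
        support[cnvr.span] = sup
        if len(sup) == 1:
            singles.append(cnvr)
            continue
        if len(sup) == 2 and not (mode == "region_all" and _region_ok(sup, sheet, region)):
            doubles.append(cnvr)
            continue
        if mode == "per_breed_min2":
            if all(
                len(sup & set(sheet.samples_of_breed(b))) >= min_per_breed
                for b in sheet.breeds
            ):
                kept.append(cnvr)
        else:
            if _region_ok(sup, sheet, region):
                kept.append(cnvr)
    return SharingResult(tuple(kept), tuple(singles), tuple(doubles), support)


def _region_ok(sup: frozenset[str], sheet: SampleSheet, region: str) -> bool:
    return set(sheet.samples_of_region(region)) <= sup


def exclusive_cnvrs(
    target: Sequence[Cnvr], others: Sequence[Sequence[Cnvr]]
) -> list[Cnvr]:
    """Target CNVRs with zero bp overlap against every other region's set.

    A CNVR is kept or dropped whole; spans are never trimmed.
    """
    other_regions = [r.span for os in others for r in os]
    by_chrom: dict[str, list[Interval]] = {}
    for iv in other_regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for cnvr in target:
        if not any(
            overlap_length(cnvr.span, iv) > 0
            for iv in by_chrom.get(cnvr.span.chrom, [])
        ):
            out.append(cnvr)
    return _sorted_cnvrs(out)


@dataclass(frozen=True)
class CnvrSummary:
    """Counts, size statistics and autosomal genome fraction of a CNVR set."""

    n_total: int
    n_gain: int
    n_loss: int
    n_both: int
    per_chrom_counts: Mapping[str, int]
    total_bp: int
    genome_fraction_pct: float
    min_length: int
    mean_length: float
    median_length: float
    max_length: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_gain + self.n_loss + self.n_both:
            raise ValueError("type counts do not partition n_total")
        if sum(self.per_chrom_counts.values()) != self.n_total:
            raise ValueError("per-chromosome counts do not sum to n_total")


def summarize_cnvrs(cnvrs: Sequence[Cnvr], build: GenomeBuild) -> CnvrSummary:
    """Summary statistics of a CNVR set against a genome build.

    ``genome_fraction_pct`` is 100 * total_bp / autosomal_length; mean and
    median lengths are rounded to 2 decimals.
    """
    if not cnvrs:
        return CnvrSummary(0, 0, 0, 0, {}, 0, 0.0, 0, 0.0, 0.0, 0)
    lengths = [r.length for r in cnvrs]
    total = sum(lengths)
    per_chrom: dict[str, int] = {}
    for r in cnvrs:
        per_chrom[r.span.chrom] = per_chrom.get(r.span.chrom, 0) + 1
    return CnvrSummary(
        n_total=len(cnvrs),
        n_gain=sum(1 for r in cnvrs if r.cnvr_type == GAIN),
        n_loss=sum(1 for r in cnvrs if r.cnvr_type == LOSS),
        n_both=sum(1 for r in cnvrs if r.cnvr_type == BOTH),
        per_chrom_counts=per_chrom,
        total_bp=total,
        genome_fraction_pct=round(100.0 * total / build.autosomal_length, 2),
        min_length=min(lengths),
        mean_length=round(total / len(lengths), 2),
        median_length=round(statistics.median(lengths), 2),
        max_length=max(lengths),
    )
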