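"""Interval algebra on 1-based fully-closed genomic intervals.

Everything downstream — reciprocal-overlap deduplication of the pooled call
set, 1-bp merging of calls into CNVRs, density trimming, exclusivity tests —
reduces to the handful of primitives in this module.  Coordinates are
1-based inclusive throughout (the VCF/GFF3 convention); BED conversion
happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Interval",
    "SupportProfile",
    "overlap_length",
    "reciprocal_overlap",
    "span_jaccard",
    "cluster_reciprocal",
    "merge_adjacent",
    "subtract_intervals",
    "support_profile",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end < start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def overlap_length(a: Interval, b: Interval) -> int:
    """Number of shared bases (0 if different chromosomes or disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """Overlap length divided by the larger of the two lengths.

    Equivalent to requiring both directional overlap fractions: the pair
    passes a threshold t iff each interval has >= t of its bases inside the
    intersection.  Symmetric; 1.0 iff the intervals are identical; 0.0 for
    different chromosomes or disjoint intervals.
    """
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return ov / max(a.length, b.length)


def span_jaccard(a: Interval, b: Interval) -> float:
    """Jaccard index of two interval spans (intersection / union of bases)."""
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return ov / (a.length + b.length - ov)


def cluster_reciprocal(
    items: Sequence[Interval], threshold: float = 0.5
) -> list[list[int]]:
    """Partition intervals by transitive closure of reciprocal overlap.

    Two intervals land in the same cluster iff they are connected by a chain
    of pairwise reciprocal overlaps >= ``threshold`` (single linkage).  The
    result is a list of clusters, each a sorted list of indices into
    ``items``; clusters are ordered by their smallest member index, so the
    partition is deterministic and independent of input order up to the
    identity of the intervals.

    Implementation: per-chromosome sorted sweep + union-find.  Only pairs
    whose intervals share at least one base can satisfy a positive
    threshold, so each interval is compared against the sweep's active set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    n = len(items)
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
    for i, iv in enumerate(items):
        by_chrom.setdefault(iv.chrom, []).append(i)

    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (items[i].start, items[i].end, i))
        active: list[int] = []  # indices whose intervals may still overlap
        for i in idxs:
            a = items[i]
            still = []
            for j in active:
                b = items[j]
                if b.end < a.start:
                    continue  # sweep has passed b
                still.append(j)
                if reciprocal_overlap(a, b) >= threshold:
                    union(i, j)
            still.append(i)
            active = still

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return [sorted(v) for _, v in sorted(clusters.items())]


def cluster_span(items: Sequence[Interval], member_idx: Iterable[int]) -> Interval:
    """Representative span of a cluster: [min start, max end]."""
    members = [items[i] for i in member_idx]
    chroms = {m.chrom for m in members}
    if len(chroms) != 1:
        raise ValueError("cluster members span multiple chromosomes")
    return Interval(
        members[0].chrom, min(m.start for m in members), max(m.end for m in members)
    )


def merge_adjacent(items: Iterable[Interval]) -> list[Interval]:
    """Merge intervals sharing >= 1 base into maximal disjoint intervals.

    Bookended intervals (end + 1 == start) are NOT merged: merging requires
    a shared base, not mere adjacency.  Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in items:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # shares a base
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


def coalesce(items: Iterable[Interval]) -> list[Interval]:
    """Union of intervals, also joining bookended neighbours (end+1 == start).

    Unlike :func:`merge_adjacent`, this rebuilds maximal contiguous runs —
    the right operation for re-assembling segments that partition a region.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in items:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e + 1:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


def subtract_intervals(
    a: Iterable[Interval], b: Iterable[Interval]
) -> list[Interval]:
    """Bases of ``a`` not covered by ``b``, as maximal intervals."""
    b_merged: dict[str, list[Interval]] = {}
    for iv in merge_adjacent(list(b)) if b else []:
        b_merged.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for iv in merge_adjacent(list(a)):
        cuts = b_merged.get(iv.chrom, [])
        pos = iv.start
        for c in cuts:
            if c.end < pos or c.start > iv.end:
                continue
            if c.start > pos:
                out.append(Interval(iv.chrom, pos, c.start - 1))
            pos = max(pos, c.end + 1)
            if pos > iv.end:
                break
        if pos <= iv.end:
            out.append(Interval(iv.chrom, pos, iv.end))
    return out


@dataclass(frozen=True)
class SupportProfile:
    """Piecewise-constant per-base count of calls covering a region.

    ``segments`` is a list of (start, end, support) triples that partition
    ``region``; boundaries fall exactly at call starts and ends.
    """

    region: Interval
    segments: tuple[tuple[int, int, int], ...]

    @property
    def max_support(self) -> int:
        return max(s for _, _, s in self.segments)

    def segments_at_least(self, min_support: int) -> list[Interval]:
        """Maximal sub-intervals whose support >= min_support."""
        kept = [
            Interval(self.region.chrom, s, e)
            for s, e, sup in self.segments
            if sup >= min_support
        ]
        return coalesce(kept) if kept else []


def support_profile(region: Interval, calls: Sequence[Interval]) -> SupportProfile:
    """Per-base support of ``region`` by ``calls`` (each must overlap it)."""
    if not calls:
        raise ValueError("support_profile: a combined region needs >= 1 call")
    events: list[tuple[int, int]] = []
    for c in calls:
        if overlap_length(c, region) == 0:
            raise ValueError(f"call {c} does not overlap region {region}")
        events.append((max(c.start, region.start), 1))
        events.append((min(c.end, region.end) + 1, -1))
    breaks = sorted({region.start, region.end + 1, *(p for p, _ in events)})
    delta: dict[int, int] = {}
    for p, d in events:
        delta[p] = delta.get(p, 0) + d
    segs: list[tuple[int, int, int]] = []
    cur = 0
    for i in range(len(breaks) - 1):
        cur += delta.get(breaks[i], 0)
        segs.append((breaks[i], breaks[i + 1] - 1, cur))
    return SupportProfile(region, tuple(segs))
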