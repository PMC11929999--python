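"""Gene/QTL overlap with CNVRs, Fisher enrichment, gene-set ORA, gene density.

QTL enrichment follows the record-counting convention: for each trait the
2x2 table counts QTL intervals (not traits) that do or do not overlap a
CNVR, against the complete QTL catalogue as background, and the one-sided
(greater) Fisher exact test asks whether the trait's QTL are
over-represented among CNVR-overlapping records.  No multiple-testing
correction drives the significance flag (p < alpha); a Benjamini-Hochberg
column is emitted alongside for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .cnvr import Cnvr
from .features import GeneModel, QtlRecord
from .genome import GenomeBuild
from .intervals import Interval, overlap_length

__all__ = [
    "EnrichmentResult",
    "overlap_features",
    "qtl_fisher_enrichment",
    "gene_set_ora",
    "GeneDensityTrack",
    "gene_density",
    "enrichment_frame",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One trait/term with its 2x2 counts and one-sided p-value.

    a: in-category & selected; b: in-category & not selected;
    c: out-of-category & selected; d: out-of-category & not selected.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    significant: bool
    bh_q: float | None = None
    gene_ratio: float | None = None

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


def _feature_interval(f) -> Interval:
    if isinstance(f, GeneModel):
        return f.span
    if isinstance(f, QtlRecord):
        return f.interval
    if isinstance(f, Interval):
        return f
    return f.interval


def overlap_features(
    cnvrs: Sequence[Cnvr], features: Sequence
) -> tuple[list[tuple[Cnvr, object]], list]:
    """Associate CNVRs with features (genes or QTL) at >= 1 bp overlap.

    Returns (associations, deduplicated feature list).  The dedup list keeps
    first-seen order, so a gene spanned by several CNVRs appears once.
    """
    by_chrom: dict[str, list[tuple[Interval, object]]] = {}
    for f in features:
        iv = _feature_interval(f)
        by_chrom.setdefault(iv.chrom, []).append((iv, f))
    assoc: list[tuple[Cnvr, object]] = []
    seen: list = []
    for cnvr in cnvrs:
        for iv, f in by_chrom.get(cnvr.span.chrom, []):
            if overlap_length(cnvr.span, iv) > 0:
                assoc.append((cnvr, f))
                if f not in seen:
                    seen.append(f)
    return assoc, seen


def qtl_fisher_enrichment(
    cnvrs: Sequence[Cnvr],
    qtl_db: Sequence[QtlRecord],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-trait over-representation of CNVR-overlapping QTL records.

    Background is the complete QTL catalogue.  For trait T:
    a = T's QTL overlapping >= 1 CNVR, b = T's QTL not overlapping,
    c = other traits' QTL overlapping, d = the rest.  One-sided (greater)
    Fisher exact p; results sorted by (p, label); significant iff p < alpha.
    """
    if not qtl_db:
        raise ValueError("empty QTL background")
    spans_by_chrom: dict[str, list[Interval]] = {}
    for r in cnvrs:
        spans_by_chrom.setdefault(r.span.chrom, []).append(r.span)
    overlapping = [
        any(
            overlap_length(q.interval, s) > 0
            for s in spans_by_chrom.get(q.chrom, [])
        )
        for q in qtl_db
    ]
    n_sel = sum(overlapping)
    total = len(qtl_db)
    traits = sorted({q.trait_name for q in qtl_db})
    results = []
    for t in traits:
        idx = [i for i, q in enumerate(qtl_db) if q.trait_name == t]
        a = sum(1 for i in idx if overlapping[i])
        b = len(idx) - a
        c = n_sel - a
        d = total - a - b - c
        p = float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        results.append((t, a, b, c, d, p))
    qs = multipletests([r[5] for r in results], method="fdr_bh")[1]
    out = [
        EnrichmentResult(t, a, b, c, d, p, p < alpha, bh_q=float(q))
        for (t, a, b, c, d, p), q in zip(results, qs)
    ]
    out.sort(key=lambda r: (r.p_value, r.label))
    return out


def gene_set_ora(
    genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a gene list in local gene sets.

    p = P(X >= k) for X ~ Hypergeom(N=|background|, K=|set n background|,
    n=|list|); the gene list must be a subset of the background and share
    its identifier namespace with the GMT.
    """
    if not genes:
        return []
    bg = set(background)
    gene_list = set(genes)
    missing = sorted(gene_list - bg)
    if missing:
        raise ValueError(f"gene(s) absent from background: {missing}")
    n_bg, n_list = len(bg), len(gene_list)
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & bg
        k = len(gene_list & members)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_list))
        results.append(
            EnrichmentResult(
                name,
                a=k,
                b=big_k - k,
                c=n_list - k,
                d=n_bg - big_k - (n_list - k),
                p_value=p,
                significant=p < alpha,
                gene_ratio=k / n_list,
            )
        )
    qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            r.label, r.a, r.b, r.c, r.d, r.p_value, r.significant,
            bh_q=float(q), gene_ratio=r.gene_ratio,
        )
        for r, q in zip(results, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.label))
    return results


@dataclass(frozen=True)
class GeneDensityTrack:
    """Gene counts in fixed-width windows tiling each chromosome."""

    window_bp: int
    frame: pd.DataFrame  # columns chrom, start, end, n_genes


def gene_density(
    genes: Sequence[GeneModel],
    build: GenomeBuild,
    window_bp: int = 1_000_000,
) -> GeneDensityTrack:
    """Count genes per window; a gene increments every window it overlaps.

    Windows tile each chromosome without gaps; the last window may be short.
    """
    rows = []
    genes_by_chrom: dict[str, list[Interval]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g.span)
    for chrom in build.chromosomes:
        start = 1
        while start <= chrom.length_bp:
            end = min(start + window_bp - 1, chrom.length_bp)
            win = Interval(chrom.name, start, end)
            n = sum(
                1
                for iv in genes_by_chrom.get(chrom.name, [])
                if overlap_length(iv, win) > 0
            )
            rows.append((chrom.name, start, end, n))
            start = end + 1
    return GeneDensityTrack(
        window_bp,
        pd.DataFrame(rows, columns=["chrom", "start", "end", "n_genes"]),
    )


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (label, a..d, p, q, significant)."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "p_value": r.p_value,
                "bh_q": r.bh_q,
                "gene_ratio": r.gene_ratio,
                "significant": r.significant,
            }
            for r in results
        ]
    )
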