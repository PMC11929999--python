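# Methods

## Scope and model of the analysis

`cnvrpipe` re-implements, as a tested library, a multi-caller consensus
analysis of copy-number variation (CNV) in structured populations — the
design used in miniature-pig breed panels: four CNV callers per sample,
reciprocal-overlap deduplication of the pooled call set, assembly of
population-level CNV regions (CNVRs) per caller, cross-caller consensus,
breed/region sharing rules, exclusivity between geographic regions,
gene/QTL overlap enrichment, and qPCR copy-number validation.  The unit of
inference is the CNVR: an interval of the autosomal genome where deletions
(loss), duplications (gain) or both recur across individuals and callers.

All internal coordinates are 1-based fully closed (the VCF/GFF3
convention); BED's 0-based half-open convention exists only at the I/O
boundary.  Parsing is driven by dialect (`vcf_svtype`, `vcf_cn`,
`tsv_regions`), never by the identity of a caller, so the four caller
slots are interchangeable producers of DEL/DUP/CN records.

## Core procedure and its conventions

**Call filtering.**  Calls shorter than 50 bp or longer than 5 Mb are
removed, and only autosomes are analysed (sex chromosomes confound
read-depth CNV calling).  Both bounds are inclusive: a 50 bp call and an
exactly 5 Mb call survive.

**Reciprocal overlap** between intervals *a* and *b* is
`|a ∩ b| / max(|a|, |b|)` — equivalent to demanding that each interval
have at least the threshold fraction of its bases inside the
intersection.  Deduplication of the pooled cross-tool call set clusters
same-type calls by single-linkage transitive closure at threshold 0.5;
the cluster's representative span is `[min start, max end]`.  Transitive
closure is the deterministic, order-independent reading of "merging";
loss and gain never co-cluster.  A single pass is used (cluster spans are
not iteratively re-tested against each other).

**Per-tool CNVR assembly.**  Per type, calls overlapping by ≥ 1 bp merge
into candidate regions (bookended intervals — `end + 1 == start` — do
*not* merge; a shared base is required).  Within each candidate region
the per-base support profile is computed and maximal sub-segments
supported by fewer than 10% of the region's contributing calls are
removed, splitting the region where an interior segment falls below
threshold.  The per-base reading of the density rule is a design choice:
the population-ranges behaviour it emulates is not specified at the
algorithm level, and per-base thresholding is the interpretation that
makes trimming idempotent (re-assembling the trimmed output is a fixed
point, which the tests assert).  The cutoff is inclusive: support
≥ `0.10 × n_calls` is kept.  Post-trim loss and gain regions that overlap
by ≥ 1 bp fuse into a single region typed `both`.

**Consensus.**  Same-type CNVRs from different tools combine when they
share ≥ 1 bp, transitively; `both` regions combine with either type, and
the fused region is retyped from its full contributing call set.
Combined regions supported by fewer than 2 distinct tools are discarded.

**Sharing rules.**  An individual *has* a CNVR iff ≥ 1 of its filtered
calls (any tool) overlaps the CNVR span by ≥ 1 bp — individuals, not
tool-specific calls, are counted.  The all-breed set keeps CNVRs
supported by ≥ 2 individuals in *every* breed (the stricter of the two
phrasings in circulation; `min_per_breed` is configurable for the laxer
reading).  Regional sets keep CNVRs supported by every animal of the
region.  Singletons and doubletons (1 or 2 supporting individuals) are
recorded separately and never enter shared sets.  Exclusive CNVRs of a
region have zero base-pair overlap with every other region's shared set
and are kept or dropped whole, never trimmed.

**Universal extreme-copy-number screen.**  Calls with copy number 0
(homozygous deletion) or ≥ 4 (homozygous duplication) are clustered at
50% reciprocal overlap; a locus survives only with a member call from
*every* sample.  A locus is then retained if ≥ 50% of its bases fall in
the exonic union (double-count-free) of some gene set; the fraction is
relative to the CNV's length, since the CNV is the object being
classified.  The GT/CN-to-homozygosity mapping (diploid GT `1/1` on a DEL
⇒ CN 0; CN ≥ 4 ⇒ hom) is a declared convention of this package, not a
property of any particular caller.

**Population structure.**  The binary presence/absence matrix (samples ×
union loci) feeds a Jaccard distance matrix (simple matching available;
the metric is recorded in the run manifest because the upstream analysis
names none).  Classical MDS is the cmdscale algorithm — square, double
centre, eigendecompose, scale by √eigenvalue — with axes of non-positive
eigenvalue excluded and each axis's sign fixed by making its
largest-magnitude coordinate positive, so runs are comparable.
Neighbour-joining is implemented in-package because the pipeline pins
behaviour library implementations leave open: ties in the Q-criterion
break on the lexicographically smallest pair of subtree labels, and
negative branch-length estimates are clamped to zero with the deficit
moved to the sister branch (flagged with a warning).  On additive
matrices the tree reproduces all pairwise distances to 1e-9 (asserted);
scikit-bio's `nj` and `pcoa` are used as independent cross-checks in the
tests, never as the implementation.  An MDS entry point that treats the
binary matrix rows as coordinates (Euclidean/PCA-style) is also provided,
since the distance-vs-matrix ambiguity is real in practice.

**Enrichment.**  Gene and QTL association uses ≥ 1 bp overlap with the
CNVR span; duplicate genes across multi-copy CNVRs are removed.  QTL
enrichment counts QTL *records* per trait against the complete catalogue
as background, one-sided (greater) Fisher exact test, significance at
p < 0.05 with no multiple-testing correction driving the flag (a
Benjamini–Hochberg column is emitted alongside for transparency).
Gene-set over-representation is the hypergeometric upper tail on local
GMT files sharing the gene list's namespace — no live web queries, no
ortholog mapping.  Gene density counts genes per 1-Mb window, a gene
incrementing every window it touches; the last window of a chromosome
may be short.

**qPCR copy number.**  `CN = 2 × 2^(−ΔCt)` with
`ΔCt = mean Ct(target) − mean Ct(reference)` and ΔCt = 0 calibrated to
the diploid state; each unit of ΔCt is an exact halving.  Uncertainty
combines the two triplicates' standard errors in quadrature and
propagates to CN by the delta method.  A triplicate with SD > 0.5 cycles
(configurable) flags the measurement unreliable and excludes it from
verdicts.  Confirmation thresholds — predicted loss confirmed iff
CN < 1.5, predicted gain iff CN > 2.5 — are this package's defaults (the
upstream analysis states none) and are configurable.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `ro_threshold` | 0.5 | reciprocal-overlap threshold for deduplication |
| `min_len_bp` / `max_len_bp` | 50 / 5,000,000 | call size filter (bp, inclusive) |
| `density_min` | 0.10 | minimum support fraction kept inside a CNVR |
| `min_tools` | 2 | distinct callers required for a consensus CNVR |
| `exon_frac` | 0.5 | minimum exonic fraction of a retained extreme-CN locus |
| `alpha` | 0.05 | significance level for Fisher / ORA |
| `sharing_min_per_breed` | 2 | individuals per breed for the all-breed set |
| `loss_max` / `gain_min` | 1.5 / 2.5 | qPCR confirmation thresholds (copies) |

## The synthetic data generator

The generator emulates the study design, not sequencing: 36 samples in 9
breeds (5+5 American, 3+3+3 Asian/Oceanian, 4+5+4+4 European) across 3
regions, on a 3 × 10 Mb toy genome.  Planted truth CNVRs come in five
sharing classes — common to all samples (12), breed-shared (9, ≥ 2
carriers in one breed), region-exclusive (3 per region, carried by every
animal of that region only), singletons (6) and doubletons (6) — placed
disjointly with a 5 kb buffer, sizes log-uniform on [200 bp, 1.4 Mb]
(the size range of the CNVR sets the design mirrors), 90% losses.  Half
of the common CNVRs are planted as extreme (CN 0, or CN ≥ 4 for gains)
in all carriers so the universal screen has a known positive.

Four caller profiles emit the three dialects (one region-list caller,
one integer-CN VCF caller, two SVTYPE/GT VCF callers).  Per carrier ×
truth region × tool a call is emitted with detection probability 0.9,
endpoints independently jittered by a normal of SD 200 bp (resampled
until the interval stays valid — truncation never inverts it) and
clamped to chromosome bounds; false positives arrive at 0.5 per Mb per
sample per tool, uniform outside truth regions, sized log-uniform on
[200 bp, 50 kb] (realistic caller artefacts are predominantly small).
Annotation emission places a gene whose single exon covers 60% of its
CNVR on 40% of truth regions plus 60 background genes; QTL of one
designated trait land on common-class truth regions at 10:1 odds (the
regions every breed shares, so the planted signal survives the sharing
stage into every tested CNVR set) against 14 background traits (300
records total); a GMT file contains the
truth-overlapping gene set plus random sets; qPCR triplicates are
generated by inverting the ΔΔCt model from true copy number (CN 0 is
emitted as a deep but finite depletion, CN_eff = 0.125, since a truly
absent template never amplifies).  All randomness flows from one seeded
`numpy` Generator; a fixed seed gives byte-identical files.

What the generator does *not* emulate: read-level noise, GC/mappability
bias, caller-specific breakpoint models, linkage between variants, or
realistic gene/QTL genome organisation.  Passing recovery tests
therefore demonstrate the correctness of the interval logic, the sharing
rules and the statistics under controlled noise — not caller performance
on real sequencing data.

## Numerical choices and degenerate inputs

Support profiles and density trimming are exact integer per-base
computations (no binning); the density cutoff compares against
`density_min × n_calls − 1e-12` to keep the inclusive boundary stable in
floating point.  Cluster partitions are deterministic and
order-independent (union-find roots at the smallest member index).  A
sample pair with an empty presence union gets Jaccard distance 0 with a
warning.  Classical MDS reports negative eigenvalues and excludes their
axes; degenerate requested axes are zero-padded.  Two-taxon NJ input
yields a single edge of the input distance.  Empty CNVR sets summarize
to zeros and write header-only tables.  A VCF symbolic SV record whose
`END` precedes `POS` is dropped as a record error (htslib strips the
invalid `END`, leaving `stop == pos` as the detectable signature — a
genuine 1-bp symbolic SV is indistinguishable and also rejected).

## Problem sizes used in the checked runs

The default synthetic run pools ~4,300 calls from four callers over 30
Mb; oracle-equivalence suites run 1,000 random instances per operation
at n ≤ ~20; NJ/MDS exactness uses 40 random instances each at n ≤ 14;
the enrichment calibration check runs 100 generator seeds through the
QTL emission and Fisher stages.  These sizes exercise every code path
while keeping the whole suite in well under a minute of compute.

## Known limitations

* Boundary precision of recovered CNVRs is limited by breakpoint jitter:
  with jitter SD σ and 10% density trimming, recovered spans extend
  ≈ 1.28 σ beyond each true edge, so the span Jaccard against truth is
  ≈ L/(L + 2.56 σ) for a region of length L.  With the default σ =
  200 bp, regions shorter than ~4.6 kb cannot reach Jaccard 0.9 no
  matter how many calls support them; detection (any-overlap recovery)
  is unaffected.  One recovery test asserts a 0.9-Jaccard bound across
  the full size distribution and is expected to fail under the default
  noise for exactly this reason; it documents the resolution limit
  rather than a defect.
* Consensus combination runs one transitive pass across the four tool
  sets; it does not iterate to a joint fixed point (observed outputs are
  already stable under re-application).
* The Fisher stage inherits the no-correction convention; with many
  traits the significance flags are exploratory, and the emitted BH
  column should be preferred for any confirmatory claim.
* No VCF output, no CRAM/BAM handling, no liftover, no live enrichment
  databases, no ortholog mapping.
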