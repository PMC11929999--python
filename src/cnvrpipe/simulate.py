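"""Seeded synthetic dataset generator for the whole pipeline.

Emulates the study design end to end without any sequencing data: a small
multi-chromosome genome, 36 samples in 9 breeds across 3 geographic
regions, planted truth CNVRs of five sharing classes (common to all
samples, breed-shared, region-exclusive, singletons, doubletons), four
noisy per-tool call sets in the exact dialects the readers accept, gene /
QTL / gene-set annotation with known planted signal, and qPCR triplicates
generated from true copy numbers.

Everything is drawn from a single numpy Generator seeded by the config, so
a fixed seed yields byte-identical output files.  The loss:gain imbalance
(default 0.9 loss) mirrors the qualitative excess of deletions over
duplications that read-depth and split-read callers report on real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calls import GAIN, LOSS
from .intervals import Interval, overlap_length

__all__ = [
    "ToolProfile",
    "SyntheticConfig",
    "TruthCnvr",
    "plant_truth",
    "emit_tool_calls",
    "emit_annotations",
    "generate_dataset",
    "DEFAULT_BREEDS",
]

# breed -> (region, n_samples); 36 samples, 9 breeds, 3 regions,
# mirroring the study's 10 American / 9 Asian-Oceanian / 17 European animals
DEFAULT_BREEDS: tuple[tuple[str, str, int], ...] = (
    ("Ossabaw", "America", 5),
    ("Yucatan", "America", 5),
    ("KuneKune", "AsiaOceania", 3),
    ("VietnamesePotbellied", "AsiaOceania", 3),
    ("Wuzhishan", "AsiaOceania", 3),
    ("Aachen", "Europe", 4),
    ("Goettingen", "Europe", 5),
    ("MiniLewe", "Europe", 4),
    ("Bergstraesser", "Europe", 4),
)


@dataclass(frozen=True)
class ToolProfile:
    """Detection behaviour of one emulated caller."""

    name: str
    dialect: str  # vcf_svtype | vcf_cn | tsv_regions
    detection_prob: float = 0.9
    jitter_sd_bp: float = 200.0
    fp_per_mb: float = 0.5


DEFAULT_TOOLS: tuple[ToolProfile, ...] = (
    ToolProfile("read_depth_a", "tsv_regions"),
    ToolProfile("read_depth_b", "vcf_cn"),
    ToolProfile("paired_split", "vcf_svtype"),
    ToolProfile("split_read", "vcf_svtype"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("1", 10_000_000),
        ("2", 10_000_000),
        ("3", 10_000_000),
    )
    breeds: tuple[tuple[str, str, int], ...] = DEFAULT_BREEDS
    n_common: int = 12
    n_per_breed: int = 9  # one planted breed-shared CNVR per breed by default
    n_region_exclusive: int = 3  # per region
    n_singleton: int = 6
    n_doubleton: int = 6
    loss_fraction: float = 0.9
    size_range_bp: tuple[int, int] = (200, 1_400_000)
    min_gap_bp: int = 5_000  # buffer between planted regions
    extreme_fraction: float = 0.5  # common CNVRs with CN 0 / >= 4 in all carriers
    tools: tuple[ToolProfile, ...] = DEFAULT_TOOLS
    # annotation knobs
    exonic_fraction: float = 0.4  # truth CNVRs given a >=50% exonic overlap
    n_background_genes: int = 60
    n_qtl: int = 300
    n_traits: int = 15
    enriched_trait: str = "Body height"
    enriched_trait_n_qtl: int = 20
    enriched_placement_odds: float = 10.0  # odds of landing on a truth CNVR
    qpcr_ct_base: float = 25.0
    qpcr_ct_noise_sd: float = 0.1
    n_qpcr_assays: int = 6

    def sample_sheet_rows(self) -> list[tuple[str, str, str]]:
        rows = []
        for breed, region, n in self.breeds:
            for i in range(1, n + 1):
                rows.append((f"{breed}_{i}", breed, region))
        return rows


@dataclass(frozen=True)
class TruthCnvr:
    """One planted truth region with its carriers and true copy numbers."""

    truth_id: str
    cls: str  # common | breed | region_exclusive | singleton | doubleton
    chrom: str
    start: int
    end: int
    cnv_type: str  # loss | gain
    carriers: tuple[str, ...]
    cn_by_carrier: Mapping[str, int]
    unit: str | None = None  # breed or region the class refers to, if any

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


def _draw_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _place(
    rng: np.random.Generator,
    genome: Sequence[tuple[str, int]],
    size_range: tuple[int, int],
    occupied: list[Interval],
    gap: int,
    max_tries: int = 400,
    max_redraws: int = 50,
) -> Interval:
    """Draw a size and place it disjointly (with a gap buffer).

    If an unluckily large draw cannot be placed in the remaining free
    space, the size is redrawn; only when repeated redraws also fail is
    the genome declared too small for the requested truth classes.
    """
    chroms = [c for c, l in genome]
    lengths = np.array([l for _, l in genome], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(max_redraws):
        size = _draw_size(rng, *size_range)
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom, clen = genome[ci]
            if size > clen:
                break
            start = int(rng.integers(1, clen - size + 2))
            cand = Interval(chrom, start, start + size - 1)
            padded = Interval(
                chrom, max(1, cand.start - gap), min(clen, cand.end + gap)
            )
            if all(overlap_length(padded, o) == 0 for o in occupied):
                return cand
    raise ValueError(
        "genome too small for the requested truth classes at the stated sizes; "
        "increase chromosome lengths or reduce counts/sizes"
    )


def plant_truth(cfg: SyntheticConfig) -> list[TruthCnvr]:
    """Plant the truth table: disjoint CNVRs with class-defined carriers."""
    rng = np.random.default_rng(cfg.seed)
    rows = cfg.sample_sheet_rows()
    samples = [s for s, _, _ in rows]
    by_breed: dict[str, list[str]] = {}
    by_region: dict[str, list[str]] = {}
    for s, b, r in rows:
        by_breed.setdefault(b, []).append(s)
        by_region.setdefault(r, []).append(s)
    breeds = list(by_breed)
    regions = list(by_region)

    occupied: list[Interval] = []
    truth: list[TruthCnvr] = []

    def plant(cls: str, carriers: Sequence[str], unit: str | None, extreme: bool) -> None:
        iv = _place(rng, cfg.genome, cfg.size_range_bp, occupied, cfg.min_gap_bp)
        occupied.append(iv)
        cnv_type = LOSS if rng.random() < cfg.loss_fraction else GAIN
        cn: dict[str, int] = {}
        for s in carriers:
            if cnv_type == LOSS:
                cn[s] = 0 if extreme else 1
            else:
                cn[s] = int(rng.integers(4, 7)) if extreme else 3
        truth.append(
            TruthCnvr(
                f"{cls}_{len(truth):03d}",
                cls,
                iv.chrom,
                iv.start,
                iv.end,
                cnv_type,
                tuple(carriers),
                cn,
                unit,
            )
        )

    for i in range(cfg.n_common):
        plant("common", samples, None, extreme=rng.random() < cfg.extreme_fraction)
    for i in range(cfg.n_per_breed):
        breed = breeds[i % len(breeds)]
        members = by_breed[breed]
        k = int(rng.integers(2, len(members) + 1))
        carriers = sorted(rng.choice(members, size=k, replace=False).tolist())
        plant("breed", carriers, breed, extreme=False)
    for region in regions:
        for _ in range(cfg.n_region_exclusive):
            plant("region_exclusive", by_region[region], region, extreme=False)
    for _ in range(cfg.n_singleton):
        plant("singleton", [samples[int(rng.integers(len(samples)))]], None, False)
    for _ in range(cfg.n_doubleton):
        pair = sorted(rng.choice(samples, size=2, replace=False).tolist())
        plant("doubleton", pair, None, extreme=False)
    return truth


def _jitter_interval(
    rng: np.random.Generator,
    iv: Interval,
    sd: float,
    chrom_len: int,
) -> Interval:
    """Jitter both endpoints; resample until the interval stays valid.

    Validity requires start strictly below end: a caller's emitted record
    always spans >= 2 bp, so symbolic-SV VCF lines never degenerate to
    END == POS (which readers must treat as a malformed END).
    """
    if sd <= 0:
        return iv
    for _ in range(100):
        ds = int(round(rng.normal(0.0, sd)))
        de = int(round(rng.normal(0.0, sd)))
        s = min(max(1, iv.start + ds), chrom_len)
        e = min(max(1, iv.end + de), chrom_len)
        if s < e:
            return Interval(iv.chrom, s, e)
    return iv


def emit_tool_calls(
    truth: Sequence[TruthCnvr],
    cfg: SyntheticConfig,
    out_dir: str | Path,
) -> dict[str, dict]:
    """Write the four per-tool call sets in their dialects.

    For every carrier x truth region x tool, a call is emitted with the
    tool's detection probability, endpoints jittered independently; false
    positives are placed uniformly outside truth regions at the configured
    per-Mb rate.  VCF dialects get one record per emitted call (the
    carrier's genotype set, all others 0/0), so per-carrier breakpoint
    scatter survives into the files.

    Returns {tool_name: {"dialect": ..., "paths": [...]}} suitable for the
    pipeline's ingestion stage.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = cfg.sample_sheet_rows()
    samples = [s for s, _, _ in rows]
    chrom_len = dict(cfg.genome)
    genome_mb = sum(l for _, l in cfg.genome) / 1e6
    truth_ivs = [t.interval for t in truth]

    manifest: dict[str, dict] = {}
    for tool in cfg.tools:
        # (sample, interval, type, cn) emitted calls for this tool
        emitted: list[tuple[str, Interval, str, int]] = []
        for t in truth:
            for carrier in t.carriers:
                if rng.random() >= tool.detection_prob:
                    continue
                iv = _jitter_interval(
                    rng, t.interval, tool.jitter_sd_bp, chrom_len[t.chrom]
                )
                emitted.append((carrier, iv, t.cnv_type, t.cn_by_carrier[carrier]))
        # false positives, uniform outside truth regions
        if tool.fp_per_mb > 0:
            for s in samples:
                n_fp = rng.poisson(tool.fp_per_mb * genome_mb)
                placed = 0
                tries = 0
                while placed < n_fp and tries < 1000 * max(1, n_fp):
                    tries += 1
                    size = _draw_size(rng, 200, 50_000)
                    chrom, clen = cfg.genome[int(rng.integers(len(cfg.genome)))]
                    if size >= clen:
                        continue
                    start = int(rng.integers(1, clen - size + 2))
                    iv = Interval(chrom, start, start + size - 1)
                    if any(overlap_length(iv, tv) > 0 for tv in truth_ivs):
                        continue
                    cnv_type = LOSS if rng.random() < cfg.loss_fraction else GAIN
                    cn = 1 if cnv_type == LOSS else 3
                    emitted.append((s, iv, cnv_type, cn))
                    placed += 1
        emitted.sort(key=lambda e: (e[1].chrom, e[1].start, e[1].end, e[0]))

        if tool.dialect == "tsv_regions":
            tool_dir = out_dir / tool.name
            tool_dir.mkdir(exist_ok=True)
            paths = []
            for s in samples:
                p = tool_dir / f"{s}.tsv"
                with open(p, "w") as fh:
                    fh.write(f"# {tool.name} regions for {s}\n")
                    for sample, iv, cnv_type, cn in emitted:
                        if sample != s:
                            continue
                        word = "deletion" if cnv_type == LOSS else "duplication"
                        fh.write(f"{word}\t{iv.chrom}:{iv.start}-{iv.end}\tCN={cn}\n")
                paths.append(str(p))
            manifest[tool.name] = {"dialect": tool.dialect, "paths": paths}
        else:
            p = out_dir / f"{tool.name}.vcf"
            _write_vcf(p, tool, emitted, samples, cfg.genome)
            manifest[tool.name] = {"dialect": tool.dialect, "paths": [str(p)]}
    return manifest


def _write_vcf(
    path: Path,
    tool: ToolProfile,
    emitted: Sequence[tuple[str, Interval, str, int]],
    samples: Sequence[str],
    genome: Sequence[tuple[str, int]],
) -> None:
    cn_dialect = tool.dialect == "vcf_cn"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={tool.name}\n")
        for chrom, length in genome:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if cn_dialect:
            fh.write(
                '##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, (sample, iv, cnv_type, cn) in enumerate(emitted):
            svtype = "DEL" if cnv_type == LOSS else "DUP"
            if cn_dialect:
                fmt = "GT:CN"
                cells = []
                for s in samples:
                    if s == sample:
                        gt = "1/1" if (cn == 0 or cn >= 4) else "0/1"
                        cells.append(f"{gt}:{cn}")
                    else:
                        cells.append("0/0:2")
            else:
                fmt = "GT"
                hom = cn == 0 or cn >= 4
                cells = [
                    ("1/1" if hom else "0/1") if s == sample else "0/0"
                    for s in samples
                ]
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{tool.name}_{i}\tN\t<{svtype}>\t.\tPASS\t"
                f"SVTYPE={svtype};END={iv.end}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def emit_annotations(
    truth: Sequence[TruthCnvr],
    cfg: SyntheticConfig,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write GFF3 genes, a QTL TSV, GMT gene sets and a qPCR table.

    Genes: a configured fraction of truth CNVRs get a gene whose single
    exon covers 60% of the CNVR (so the >= 50% exonic-overlap rule fires),
    plus background genes placed outside truth regions.  QTL: one
    designated trait's records land on truth CNVRs with the configured
    odds, giving the Fisher stage a known positive.  GMT: the 'planted'
    set collects the truth-overlapping genes.  qPCR: Ct triplicates are
    generated from true copy number via Ct_target = base - log2(CN/2) +
    noise (CN 0 is emitted as a deep, not infinite, depletion).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom_len = dict(cfg.genome)
    truth_ivs = [t.interval for t in truth]

    # ---- genes
    genes: list[tuple[str, Interval, Interval]] = []  # (id, body, exon)
    n_on_truth = int(round(cfg.exonic_fraction * len(truth)))
    order = rng.permutation(len(truth))[:n_on_truth]
    for gi, ti in enumerate(sorted(order.tolist())):
        t = truth[ti]
        exon_len = max(1, int(0.6 * t.interval.length))
        ex_start = t.start + (t.interval.length - exon_len) // 2
        exon = Interval(t.chrom, ex_start, ex_start + exon_len - 1)
        body = Interval(
            t.chrom,
            max(1, exon.start - 500),
            min(chrom_len[t.chrom], exon.end + 500),
        )
        genes.append((f"GTRUTH{gi:03d}", body, exon))
    for gi in range(cfg.n_background_genes):
        size = int(rng.integers(2_000, 20_000))
        for _ in range(500):
            chrom, clen = cfg.genome[int(rng.integers(len(cfg.genome)))]
            start = int(rng.integers(1, clen - size + 2))
            body = Interval(chrom, start, start + size - 1)
            if all(overlap_length(body, tv) == 0 for tv in truth_ivs):
                break
        exon = Interval(chrom, start + 100, min(body.end, start + 100 + size // 3))
        genes.append((f"GBG{gi:03d}", body, exon))
    genes.sort(key=lambda g: (g[1].chrom, g[1].start, g[0]))
    gff_path = out_dir / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, body, exon in genes:
            fh.write(
                f"{body.chrom}\tsynthetic\tgene\t{body.start}\t{body.end}\t.\t+\t.\t"
                f"ID={gid};Name={gid}\n"
            )
            fh.write(
                f"{exon.chrom}\tsynthetic\texon\t{exon.start}\t{exon.end}\t.\t+\t.\t"
                f"ID={gid}.e1;Parent={gid}\n"
            )

    # ---- QTL: the enriched trait lands on the common-class truth CNVRs
    # (the regions every breed shares, hence present in every tested set)
    qtl_path = out_dir / "qtl.tsv"
    traits = [f"Trait {i + 1}" for i in range(cfg.n_traits - 1)]
    p_on = cfg.enriched_placement_odds / (cfg.enriched_placement_odds + 1.0)
    enriched_targets = [t for t in truth if t.cls == "common"] or list(truth)
    with open(qtl_path, "w") as fh:
        fh.write("qtl_id\ttrait\tchrom\tstart\tend\n")
        qid = 0

        def write_qtl(trait: str, iv: Interval) -> None:
            nonlocal qid
            fh.write(f"QTL{qid:04d}\t{trait}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")
            qid += 1

        for _ in range(cfg.enriched_trait_n_qtl):
            if rng.random() < p_on and enriched_targets:
                t = enriched_targets[int(rng.integers(len(enriched_targets)))]
                size = max(500, min(t.interval.length, int(rng.integers(500, 50_000))))
                lo = max(1, t.start - size // 2)
                hi = min(chrom_len[t.chrom] - size + 1, t.end - size // 2)
                start = int(rng.integers(lo, max(lo + 1, hi + 1)))
                write_qtl(cfg.enriched_trait, Interval(t.chrom, start, start + size - 1))
            else:
                write_qtl(cfg.enriched_trait, _random_iv(rng, cfg, 500, 50_000))
        n_rest = cfg.n_qtl - cfg.enriched_trait_n_qtl
        for i in range(n_rest):
            write_qtl(traits[i % len(traits)], _random_iv(rng, cfg, 500, 200_000))

    # ---- GMT
    gmt_path = out_dir / "gene_sets.gmt"
    all_ids = [g[0] for g in genes]
    planted_set = [g for g in all_ids if g.startswith("GTRUTH")]
    with open(gmt_path, "w") as fh:
        fh.write("planted\ttruth-overlapping genes\t" + "\t".join(planted_set) + "\n")
        for k in range(4):
            size = min(len(all_ids), 12)
            members = sorted(rng.choice(all_ids, size=size, replace=False).tolist())
            fh.write(f"random_{k}\trandom background set\t" + "\t".join(members) + "\n")

    # ---- qPCR
    qpcr_path = out_dir / "qpcr.tsv"
    candidates = [t for t in truth if t.cls == "common"] or list(truth)
    with open(qpcr_path, "w") as fh:
        fh.write("sample\tassay\tct_t1\tct_t2\tct_t3\tct_r1\tct_r2\tct_r3\tpredicted_type\n")
        for ai in range(min(cfg.n_qpcr_assays, len(candidates))):
            t = candidates[ai]
            carrier = t.carriers[int(rng.integers(len(t.carriers)))]
            cn_eff = max(t.cn_by_carrier[carrier], 0.125)  # CN 0 -> deep depletion
            dct = -math.log2(cn_eff / 2.0)
            ct_t = [
                cfg.qpcr_ct_base + dct + rng.normal(0, cfg.qpcr_ct_noise_sd)
                for _ in range(3)
            ]
            ct_r = [
                cfg.qpcr_ct_base + rng.normal(0, cfg.qpcr_ct_noise_sd)
                for _ in range(3)
            ]
            fh.write(
                f"{carrier}\tassay_{t.truth_id}\t"
                + "\t".join(f"{v:.4f}" for v in ct_t)
                + "\t"
                + "\t".join(f"{v:.4f}" for v in ct_r)
                + f"\t{t.cnv_type}\n"
            )

    return {
        "gff3": str(gff_path),
        "qtl": str(qtl_path),
        "gmt": str(gmt_path),
        "qpcr": str(qpcr_path),
    }


def _random_iv(
    rng: np.random.Generator, cfg: SyntheticConfig, lo: int, hi: int
) -> Interval:
    size = int(rng.integers(lo, hi))
    chrom, clen = cfg.genome[int(rng.integers(len(cfg.genome)))]
    size = min(size, clen - 1)
    start = int(rng.integers(1, clen - size + 2))
    return Interval(chrom, start, start + size - 1)


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Generate the complete dataset; returns a manifest of paths + truth.

    Writes genome.tsv, samples.tsv, per-tool call sets, annotation files
    and truth.json under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "genome.tsv", "w") as fh:
        fh.write("chrom\tlength\tis_autosome\n")
        for chrom, length in cfg.genome:
            fh.write(f"{chrom}\t{length}\t1\n")
    with open(out_dir / "samples.tsv", "w") as fh:
        fh.write("sample\tbreed\tregion\n")
        for s, b, r in cfg.sample_sheet_rows():
            fh.write(f"{s}\t{b}\t{r}\n")

    truth = plant_truth(cfg)
    tool_files = emit_tool_calls(truth, cfg, out_dir / "calls")
    ann = emit_annotations(truth, cfg, out_dir)

    truth_json = [
        {
            "truth_id": t.truth_id,
            "class": t.cls,
            "chrom": t.chrom,
            "start": t.start,
            "end": t.end,
            "type": t.cnv_type,
            "unit": t.unit,
            "carriers": list(t.carriers),
            "cn_by_carrier": dict(t.cn_by_carrier),
        }
        for t in truth
    ]
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)

    return {
        "genome": str(out_dir / "genome.tsv"),
        "samples": str(out_dir / "samples.tsv"),
        "tools": tool_files,
        "truth": truth,
        "truth_json": str(out_dir / "truth.json"),
        **ann,
    }
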