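"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 1-based fully closed everywhere (the VCF/GFF3
convention); BED's 0-based half-open convention is converted only at this
boundary.  Caller outputs come in three dialects — ``vcf_svtype`` (SVTYPE/
END/GT records, Delly/Smoove style), ``vcf_cn`` (per-sample integer CN
genotypes, GATK gCNV style) and ``tsv_regions`` (per-sample region lists,
CNVpytor style) — and parsing is driven by the dialect, never by the tool
name.  Malformed records are dropped and reported, never silently fixed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from skbio import TreeNode

from .calls import GAIN, LOSS, CnvCall, classify_call_type
from .cnvr import Cnvr
from .features import GeneModel, QtlRecord
from .genome import GenomeBuild
from .intervals import Interval
from .qpcr import QpcrMeasurement

DIALECTS = ("vcf_svtype", "vcf_cn", "tsv_regions")

__all__ = [
    "DIALECTS",
    "IngestReport",
    "read_cnv_calls",
    "read_annotations",
    "read_gff3_genes",
    "read_qtl",
    "read_gmt",
    "read_qpcr_table",
    "write_cnvr_bed",
    "write_cnvr_tsv",
    "read_cnvr_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_newick",
    "read_newick",
    "write_mds_tsv",
]


@dataclass
class IngestReport:
    """Per-file ingestion bookkeeping: warnings are counted, errors listed."""

    path: str
    n_read: int = 0
    n_kept: int = 0
    warnings: dict[str, int] = field(default_factory=dict)
    record_errors: list[tuple[int, str]] = field(default_factory=list)

    def warn(self, reason: str) -> None:
        self.warnings[reason] = self.warnings.get(reason, 0) + 1

    def error(self, line: int, message: str) -> None:
        self.record_errors.append((line, message))


# ---------------------------------------------------------------- CNV calls


def read_cnv_calls(
    path: str | Path,
    tool: str,
    dialect: str,
    build: GenomeBuild,
    sample_id: str | None = None,
) -> tuple[list[CnvCall], IngestReport]:
    """Read one caller's output file into normalized :class:`CnvCall` records.

    ``sample_id`` is required for the per-sample ``tsv_regions`` dialect and
    ignored for the multi-sample VCF dialects.  Records on chromosomes
    absent from ``build`` are rejected with a counted warning; records with
    END < POS are dropped with a line-numbered record error.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = IngestReport(str(path))
    if dialect == "tsv_regions":
        if sample_id is None:
            raise ValueError("tsv_regions dialect needs a sample_id")
        calls = _read_tsv_regions(path, tool, sample_id, build, report)
    else:
        calls = _read_vcf(path, tool, dialect, build, report)
    report.n_kept = len(calls)
    return calls, report


_TYPE_WORDS = {
    "deletion": LOSS, "del": LOSS, "loss": LOSS,
    "duplication": GAIN, "dup": GAIN, "gain": GAIN,
}
_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _read_tsv_regions(
    path: Path, tool: str, sample_id: str, build: GenomeBuild, report: IngestReport
) -> list[CnvCall]:
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            report.n_read += 1
            fields = line.split("\t")
            if len(fields) < 2:
                report.error(lineno, "expected >= 2 tab-separated fields")
                continue
            type_word = fields[0].strip().lower()
            if type_word not in _TYPE_WORDS:
                report.warn("unknown_region_type")
                continue
            m = _REGION_RE.match(fields[1].strip())
            if not m:
                report.error(lineno, f"unparseable region {fields[1]!r}")
                continue
            chrom = m.group("chrom")
            start, end = int(m.group("start")), int(m.group("end"))
            if end < start:
                report.error(lineno, f"END {end} < POS {start}")
                continue
            if chrom not in build:
                report.warn("unknown_chromosome")
                continue
            cn: int | None = None
            for extra in fields[2:]:
                extra = extra.strip()
                if extra.upper().startswith("CN="):
                    cn = int(extra[3:])
            cnv_type = _TYPE_WORDS[type_word]
            if cn is not None and classify_call_type(copy_number=cn) != cnv_type:
                report.error(lineno, f"CN={cn} inconsistent with type {cnv_type}")
                continue
            genotype = "unknown"
            if cn is not None:
                genotype = "hom" if (cn == 0 or cn >= 4) else "het"
            calls.append(
                CnvCall(sample_id, tool, chrom, start, end, cnv_type, cn, genotype)
            )
    return calls


def _read_vcf(
    path: Path, tool: str, dialect: str, build: GenomeBuild, report: IngestReport
) -> list[CnvCall]:
    calls: list[CnvCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            report.n_read += 1
            start = rec.pos  # 1-based
            end = rec.stop  # pysam: 0-based exclusive == 1-based inclusive end
            # htslib hoists INFO/END into rec.stop and DROPS an END < POS;
            # a symbolic SV record left with stop == pos is that malformed
            # case (a true 1-bp symbolic SV is indistinguishable and also
            # rejected here)
            symbolic = bool(rec.alts) and rec.alts[0].startswith("<")
            if end < start or (symbolic and end == start):
                report.error(rec.pos, f"missing or invalid END (END < POS {start}?)")
                continue
            if rec.chrom not in build:
                report.warn("unknown_chromosome")
                continue
            if dialect == "vcf_svtype":
                svtype = rec.info.get("SVTYPE")
                if svtype not in ("DEL", "DUP"):
                    report.warn(f"skipped_svtype_{svtype}")
                    continue
                cnv_type = classify_call_type(svtype=svtype)
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or not any(a == 1 for a in gt if a is not None):
                        continue
                    hom = all(a == 1 for a in gt if a is not None) and len(gt) > 1
                    genotype = "hom" if hom else "het"
                    cn: int | None = None
                    if cnv_type == LOSS:
                        cn = 0 if hom else 1
                    calls.append(
                        CnvCall(s, tool, rec.chrom, start, end, cnv_type, cn, genotype)
                    )
            else:  # vcf_cn
                for s in samples:
                    cn = rec.samples[s].get("CN")
                    if cn is None or int(cn) == 2:
                        continue
                    cn = int(cn)
                    cnv_type = classify_call_type(copy_number=cn)
                    genotype = "hom" if (cn == 0 or cn >= 4) else "het"
                    calls.append(
                        CnvCall(s, tool, rec.chrom, start, end, cnv_type, cn, genotype)
                    )
    return calls


# -------------------------------------------------------------- annotations


def read_gff3_genes(
    path: str | Path, build: GenomeBuild
) -> tuple[list[GeneModel], IngestReport]:
    """Read gene models (genes + Parent-linked exons) from a GFF3 file.

    Exons are grouped under their gene (directly or through an mRNA level);
    exons with a dangling Parent are dropped with a counted warning, and a
    gene without exons is skipped with a warning.
    """
    report = IngestReport(str(path))
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    exons_by_gene: dict[str, list[Interval]] = {}
    for ex in db.features_of_type("exon"):
        report.n_read += 1
        owner = None
        for pid in ex.attributes.get("Parent", []):
            if pid in gene_ids:
                owner = pid
                break
            try:
                parent = db[pid]
            except gffutils.FeatureNotFoundError:
                continue
            for anc in db.parents(parent, featuretype="gene"):
                owner = anc.id
                break
            if owner is None and parent.featuretype == "gene":
                owner = parent.id
            if owner:
                break
        if owner is None:
            report.warn("orphan_exon")
            continue
        exons_by_gene.setdefault(owner, []).append(
            Interval(ex.seqid, ex.start, ex.end)
        )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.seqid not in build:
            report.warn("unknown_chromosome")
            continue
        exons = exons_by_gene.get(g.id)
        if not exons:
            report.warn("gene_without_exons")
            continue
        symbol = (g.attributes.get("Name") or [None])[0]
        strand = g.strand if g.strand in ("+", "-") else "unknown"
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                exons=tuple(sorted(exons)),
                symbol=symbol,
                strand=strand,
                body=Interval(g.seqid, g.start, g.end),
            )
        )
    report.n_kept = len(genes)
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return genes, report


def _strip_chr(chrom: str) -> str:
    for pre in ("Chr.", "chr.", "Chr", "chr"):
        if chrom.startswith(pre):
            return chrom[len(pre):]
    return chrom


def read_qtl(path: str | Path, build: GenomeBuild) -> tuple[list[QtlRecord], IngestReport]:
    """Read a QTL table in either the GFF-like dialect or a plain TSV.

    The GFF-like dialect (Animal QTLdb export style) carries the trait in a
    ``trait=``/``Name=`` attribute of column 9; the TSV dialect has columns
    ``qtl_id``, ``trait``, ``chrom``, ``start``, ``end``.  Trait names are
    kept verbatim.  Records without a trait name are record errors; records
    on chromosomes absent from the build are dropped with a warning.
    """
    path = Path(path)
    report = IngestReport(str(path))
    with open(path) as fh:
        lines = fh.readlines()
    body = [l for l in lines if l.strip() and not l.startswith("#")]
    is_gff = bool(body) and len(body[0].rstrip("\n").split("\t")) >= 9
    records: list[QtlRecord] = []
    if is_gff:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            report.n_read += 1
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                report.error(lineno, "expected 9 GFF columns")
                continue
            attrs = {}
            for kv in f[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip()] = v.strip().strip('"')
            trait = attrs.get("trait") or attrs.get("Name")
            if not trait:
                report.error(lineno, "QTL without trait name")
                continue
            qtl_id = attrs.get("QTL_ID") or attrs.get("ID") or f"qtl_line{lineno}"
            chrom = _strip_chr(f[0])
            if chrom not in build:
                report.warn("unknown_chromosome")
                continue
            try:
                start, end = int(float(f[3])), int(float(f[4]))
            except ValueError:
                report.error(lineno, "unparseable coordinates")
                continue
            if end < start:
                report.error(lineno, f"END {end} < POS {start}")
                continue
            records.append(QtlRecord(qtl_id, trait, chrom, start, end))
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = {"qtl_id", "trait", "chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"QTL TSV {path}: missing columns {sorted(missing)}")
        for i, r in enumerate(df.itertuples(), start=2):
            report.n_read += 1
            trait = str(r.trait) if pd.notna(r.trait) else ""
            if not trait:
                report.error(i, "QTL without trait name")
                continue
            chrom = _strip_chr(str(r.chrom))
            if chrom not in build:
                report.warn("unknown_chromosome")
                continue
            start, end = int(r.start), int(r.end)
            if end < start:
                report.error(i, f"END {end} < POS {start}")
                continue
            records.append(QtlRecord(str(r.qtl_id), trait, chrom, start, end))
    report.n_kept = len(records)
    return records, report


def read_annotations(
    gff3_path: str | Path, qtl_path: str | Path, build: GenomeBuild
) -> tuple[list[GeneModel], list[QtlRecord], IngestReport, IngestReport]:
    """Read gene models and QTL records together (convenience wrapper)."""
    genes, gene_report = read_gff3_genes(gff3_path, build)
    qtl, qtl_report = read_qtl(qtl_path, build)
    return genes, qtl, gene_report, qtl_report


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: tab-separated set name, description, gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3 or not f[0]:
                continue
            sets[f[0]] = [g for g in f[2:] if g]
    return sets


def read_qpcr_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read qPCR triplicates: sample, assay, ct_t1..3, ct_r1..3, predicted_type."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "assay": str})
    need = {"sample", "assay", "ct_t1", "ct_t2", "ct_t3", "ct_r1", "ct_r2", "ct_r3"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table {path}: missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples():
        predicted = getattr(r, "predicted_type", None)
        if pd.isna(predicted) or predicted == "":
            predicted = None
        out.append(
            QpcrMeasurement(
                sample_id=str(r.sample),
                assay_id=str(r.assay),
                ct_target=(float(r.ct_t1), float(r.ct_t2), float(r.ct_t3)),
                ct_reference=(float(r.ct_r1), float(r.ct_r2), float(r.ct_r3)),
                predicted_type=predicted,
            )
        )
    return out


# ------------------------------------------------------------------ writers


def write_cnvr_bed(cnvrs: Sequence[Cnvr], path: str | Path) -> None:
    """Emit CNVRs as BED4 (0-based half-open; name column = type)."""
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(
                f"{r.span.chrom}\t{r.span.start - 1}\t{r.span.end}\t{r.cnvr_type}\n"
            )


def write_cnvr_tsv(cnvrs: Sequence[Cnvr], path: str | Path) -> None:
    """Emit CNVRs as TSV (1-based inclusive, with support columns)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\ttools\tsamples\tn_calls\n")
        for r in cnvrs:
            fh.write(
                "\t".join(
                    [
                        r.span.chrom,
                        str(r.span.start),
                        str(r.span.end),
                        r.cnvr_type,
                        ",".join(sorted(r.tools)),
                        ",".join(sorted(r.samples)),
                        str(r.n_calls),
                    ]
                )
                + "\n"
            )


def read_cnvr_tsv(path: str | Path) -> list[Cnvr]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples():
        out.append(
            Cnvr(
                span=Interval(str(r.chrom), int(r.start), int(r.end)),
                cnvr_type=str(r.type),
                tools=frozenset(str(r.tools).split(",")),
                samples=frozenset(str(r.samples).split(",")) if pd.notna(r.samples) else frozenset(),
                n_calls=int(r.n_calls),
            )
        )
    return out


def write_calls_tsv(calls: Sequence[CnvCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttool\tchrom\tstart\tend\ttype\tcopy_number\tgenotype\n")
        for c in calls:
            cn = "" if c.copy_number is None else str(c.copy_number)
            fh.write(
                f"{c.sample_id}\t{c.tool}\t{c.chrom}\t{c.start}\t{c.end}\t"
                f"{c.cnv_type}\t{cn}\t{c.genotype}\n"
            )


def read_calls_tsv(path: str | Path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    out = []
    for r in df.itertuples():
        cn = None if pd.isna(r.copy_number) else int(r.copy_number)
        out.append(
            CnvCall(
                str(r.sample), str(r.tool), str(r.chrom), int(r.start), int(r.end),
                str(r.type), cn, str(r.genotype),
            )
        )
    return out


def write_matrix_tsv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    import numpy as np

    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.index.name = "sample"
    return m.astype(np.int8)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_mds_tsv(
    coords: pd.DataFrame, sheet, path: str | Path
) -> None:
    """MDS coordinates with breed/region columns joined from the sheet."""
    df = coords.copy()
    df["breed"] = [sheet.breed_of(s) for s in df.index]
    df["region"] = [sheet.region_of(s) for s in df.index]
    df.to_csv(path, sep="\t")
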