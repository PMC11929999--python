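"""End-to-end orchestration: ingest -> CNVRs -> structure -> enrichment.

The pipeline runs the full chain in a fixed stage order and writes every
table through the io module, together with a machine-readable manifest
(config hash, seed, package versions, per-stage record counts).  The
manifest carries no timestamps, so identical config + seed reruns produce
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .calls import (
    CnvCall,
    FilterConfig,
    build_union_loci,
    exon_overlap_select,
    extract_extreme_cn_shared,
    filter_calls,
)
from .cnvr import (
    Cnvr,
    SharingResult,
    build_tool_cnvrs,
    consensus_cnvrs,
    exclusive_cnvrs,
    shared_cnvrs,
    summarize_cnvrs,
)
from .enrichment import (
    enrichment_frame,
    gene_set_ora,
    overlap_features,
    qtl_fisher_enrichment,
)
from .genome import GenomeBuild, read_genome_table
from . import io as io_formats
from .popstruct import binary_matrix, classical_mds, distance_matrix, neighbor_joining
from .qpcr import concordance, estimate_copy_number
from .samples import SampleSheet, read_sample_sheet
from .simulate import SyntheticConfig, generate_dataset

log = logging.getLogger("cnvrpipe")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    # inputs: either synthetic config, or explicit paths
    synthetic: SyntheticConfig | None = None
    genome_table: str | None = None
    sample_sheet: str | None = None
    tool_inputs: Mapping[str, Mapping] | None = None  # tool -> {dialect, paths}
    gff3: str | None = None
    qtl: str | None = None
    gmt: str | None = None
    qpcr: str | None = None
    # thresholds (study conventions)
    ro_threshold: float = 0.5
    min_len_bp: int = 50
    max_len_bp: int = 5_000_000
    density_min: float = 0.10
    min_tools: int = 2
    exon_frac: float = 0.5
    alpha: float = 0.05
    # mode flags
    sharing_min_per_breed: int = 2
    distance_metric: str = "jaccard"

    def __post_init__(self) -> None:
        if not 0 < self.ro_threshold <= 1:
            raise ValueError("ro_threshold must be in (0,1]")
        if not 0 <= self.density_min < 1:
            raise ValueError("density_min must be in [0,1)")
        if not 0 < self.exon_frac <= 1:
            raise ValueError("exon_frac must be in (0,1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.min_tools < 1:
            raise ValueError("min_tools must be >= 1")
        if self.synthetic is None and not (
            self.genome_table and self.sample_sheet and self.tool_inputs
        ):
            raise ValueError(
                "need either a synthetic block or genome_table + sample_sheet "
                "+ tool_inputs"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        syn = raw.get("synthetic")
        if isinstance(syn, dict):
            syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
            syn_unknown = set(syn) - syn_known
            if syn_unknown:
                raise ValueError(f"unknown synthetic keys: {sorted(syn_unknown)}")
            if "genome" in syn:
                syn["genome"] = tuple((str(c), int(l)) for c, l in syn["genome"])
            if "breeds" in syn:
                syn["breeds"] = tuple(
                    (str(b), str(r), int(n)) for b, r, n in syn["breeds"]
                )
            raw["synthetic"] = SyntheticConfig(**syn)
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (out_dir excluded, so the same
        analysis written to two places yields byte-identical outputs)."""

        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the run computed, in memory, plus the output directory."""

    config: RunConfig
    build: GenomeBuild
    sheet: SampleSheet
    calls_by_tool: dict[str, list[CnvCall]]
    filtered_by_tool: dict[str, list[CnvCall]]
    union_loci: list
    matrix: "object"
    mds: "object"
    tree: "object"
    extreme_exonic: list
    tool_cnvrs: dict[str, list[Cnvr]]
    consensus: list[Cnvr]
    shared_all_breeds: SharingResult
    shared_by_region: dict[str, SharingResult]
    exclusive_by_region: dict[str, list[Cnvr]]
    summaries: dict[str, "object"]
    qtl_enrichment: list = field(default_factory=list)
    ora: list = field(default_factory=list)
    qpcr_estimates: list = field(default_factory=list)
    qpcr_verdicts: dict = field(default_factory=dict)
    genes: list = field(default_factory=list)
    qtl: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _ingest_tool(
    tool: str, source: Mapping, build: GenomeBuild
) -> tuple[list[CnvCall], dict]:
    dialect = source["dialect"]
    calls: list[CnvCall] = []
    warnings: dict[str, int] = {}
    for p in source["paths"]:
        sample_id = Path(p).stem if dialect == "tsv_regions" else None
        got, report = io_formats.read_cnv_calls(
            p, tool, dialect, build, sample_id=sample_id
        )
        calls.extend(got)
        for k, v in report.warnings.items():
            warnings[k] = warnings.get(k, 0) + v
        if report.record_errors:
            for line, msg in report.record_errors:
                log.warning("%s line %s: %s", p, line, msg)
    return calls, warnings


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis chain; write tables + manifest to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    # ---- stage: inputs (synthetic generation feeds the ordinary readers)
    if cfg.synthetic is not None:
        syn_cfg = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        ds = generate_dataset(syn_cfg, out / "synthetic")
        genome_table, sample_sheet = ds["genome"], ds["samples"]
        tool_inputs = ds["tools"]
        gff3, qtl_path, gmt_path, qpcr_path = (
            ds["gff3"], ds["qtl"], ds["gmt"], ds["qpcr"],
        )
    else:
        genome_table, sample_sheet = cfg.genome_table, cfg.sample_sheet
        tool_inputs = cfg.tool_inputs
        gff3, qtl_path, gmt_path, qpcr_path = cfg.gff3, cfg.qtl, cfg.gmt, cfg.qpcr

    build = read_genome_table(genome_table)
    sheet = read_sample_sheet(sample_sheet)
    counts["samples"] = len(sheet.samples)
    counts["breeds"] = len(sheet.breeds)

    calls_by_tool: dict[str, list[CnvCall]] = {}
    for tool, source in tool_inputs.items():
        calls_by_tool[tool], warn = _ingest_tool(tool, source, build)
        counts[f"calls_raw_{tool}"] = len(calls_by_tool[tool])
        if warn:
            counts[f"warnings_{tool}"] = warn
    if len(calls_by_tool) < cfg.min_tools:
        raise RuntimeError(
            f"stage ingest: fewer than {cfg.min_tools} tool call sets"
        )

    # ---- stage: filter
    fcfg = FilterConfig(cfg.min_len_bp, cfg.max_len_bp, autosomes_only=True)
    filtered_by_tool: dict[str, list[CnvCall]] = {}
    for tool, calls in calls_by_tool.items():
        kept, removed = filter_calls(calls, build, fcfg)
        filtered_by_tool[tool] = kept
        counts[f"calls_filtered_{tool}"] = len(kept)
        counts[f"removed_{tool}"] = removed
    pooled = [c for calls in filtered_by_tool.values() for c in calls]
    io_formats.write_calls_tsv(pooled, out / "calls_filtered.tsv")

    # ---- stage: union loci + population structure
    loci = build_union_loci(pooled, cfg.ro_threshold)
    counts["union_loci"] = len(loci)
    matrix = binary_matrix(loci, sheet)
    io_formats.write_matrix_tsv(matrix, out / "binary_matrix.tsv")
    dm = distance_matrix(matrix, cfg.distance_metric)
    mds = classical_mds(dm, k=2)
    io_formats.write_mds_tsv(mds.coordinates, sheet, out / "mds_coordinates.tsv")
    tree = neighbor_joining(dm)
    io_formats.write_newick(tree, out / "nj_tree.nwk")

    # ---- stage: universal extreme-CN exonic set
    genes, qtl = [], []
    if gff3:
        genes, _ = io_formats.read_gff3_genes(gff3, build)
        counts["genes"] = len(genes)
    extreme = extract_extreme_cn_shared(pooled, sheet.samples, cfg.ro_threshold)
    counts["extreme_cn_universal_loci"] = len(extreme)
    extreme_exonic = exon_overlap_select(extreme, genes, cfg.exon_frac) if genes else []
    counts["extreme_cn_exonic"] = len(extreme_exonic)
    with open(out / "extreme_cn_exonic.tsv", "w") as fh:
        fh.write("locus\ttype\tn_genes\tgenes\n")
        for locus, glist, _ in extreme_exonic:
            fh.write(
                f"{locus.span.chrom}:{locus.span.start}-{locus.span.end}\t"
                f"{locus.cnv_type}\t{len(glist)}\t"
                + ",".join(g.gene_id for g in glist)
                + "\n"
            )

    # ---- stage: per-tool CNVRs + consensus
    tool_cnvrs = {
        tool: build_tool_cnvrs(calls, cfg.density_min)
        for tool, calls in filtered_by_tool.items()
    }
    for tool, regions in tool_cnvrs.items():
        counts[f"cnvrs_{tool}"] = len(regions)
    consensus = consensus_cnvrs(list(tool_cnvrs.values()), cfg.min_tools)
    counts["cnvrs_consensus"] = len(consensus)
    io_formats.write_cnvr_tsv(consensus, out / "cnvrs_consensus.tsv")
    io_formats.write_cnvr_bed(consensus, out / "cnvrs_consensus.bed")

    # ---- stage: sharing rules
    shared_all = shared_cnvrs(
        consensus, pooled, sheet, "per_breed_min2",
        min_per_breed=cfg.sharing_min_per_breed,
    )
    counts["cnvrs_shared_all_breeds"] = len(shared_all.kept)
    counts["singletons"] = len(shared_all.singletons)
    counts["doubletons"] = len(shared_all.doubletons)
    io_formats.write_cnvr_tsv(shared_all.kept, out / "cnvrs_shared_all_breeds.tsv")
    shared_by_region: dict[str, SharingResult] = {}
    for region in sheet.regions:
        res = shared_cnvrs(consensus, pooled, sheet, "region_all", region=region)
        shared_by_region[region] = res
        counts[f"cnvrs_region_{region}"] = len(res.kept)
        io_formats.write_cnvr_tsv(res.kept, out / f"cnvrs_region_{region}.tsv")

    # ---- stage: exclusive CNVRs
    exclusive_by_region: dict[str, list[Cnvr]] = {}
    for region in sheet.regions:
        others = [
            shared_by_region[r].kept for r in sheet.regions if r != region
        ]
        exclusive_by_region[region] = exclusive_cnvrs(
            shared_by_region[region].kept, others
        )
        counts[f"cnvrs_exclusive_{region}"] = len(exclusive_by_region[region])
        io_formats.write_cnvr_tsv(
            exclusive_by_region[region], out / f"cnvrs_exclusive_{region}.tsv"
        )

    # ---- stage: summaries
    summaries = {"shared_all_breeds": summarize_cnvrs(shared_all.kept, build)}
    for region in sheet.regions:
        summaries[f"region_{region}"] = summarize_cnvrs(
            shared_by_region[region].kept, build
        )
        summaries[f"exclusive_{region}"] = summarize_cnvrs(
            exclusive_by_region[region], build
        )
    with open(out / "cnvr_summaries.tsv", "w") as fh:
        fh.write(
            "set\tn_total\tn_gain\tn_loss\tn_both\ttotal_bp\t"
            "genome_fraction_pct\tmin_len\tmean_len\tmedian_len\tmax_len\n"
        )
        for name, s in summaries.items():
            fh.write(
                f"{name}\t{s.n_total}\t{s.n_gain}\t{s.n_loss}\t{s.n_both}\t"
                f"{s.total_bp}\t{s.genome_fraction_pct}\t{s.min_length}\t"
                f"{s.mean_length}\t{s.median_length}\t{s.max_length}\n"
            )

    # ---- stage: gene/QTL overlap + enrichment
    qtl_enrichment, ora = [], []
    if qtl_path:
        qtl, _ = io_formats.read_qtl(qtl_path, build)
        counts["qtl_records"] = len(qtl)
        qtl_enrichment = qtl_fisher_enrichment(shared_all.kept, qtl, cfg.alpha)
        enrichment_frame(qtl_enrichment).to_csv(
            out / "qtl_enrichment.tsv", sep="\t", index=False
        )
        counts["qtl_traits_significant"] = sum(
            1 for r in qtl_enrichment if r.significant
        )
    if gmt_path and genes:
        gene_sets = io_formats.read_gmt(gmt_path)
        _, cnvr_genes = overlap_features(shared_all.kept, genes)
        gene_ids = [g.gene_id for g in cnvr_genes]
        background = [g.gene_id for g in genes]
        counts["cnvr_genes"] = len(gene_ids)
        ora = gene_set_ora(gene_ids, gene_sets, background, cfg.alpha)
        enrichment_frame(ora).to_csv(out / "gene_set_ora.tsv", sep="\t", index=False)

    # ---- stage: qPCR
    qpcr_estimates, qpcr_verdicts = [], {}
    if qpcr_path:
        measurements = io_formats.read_qpcr_table(qpcr_path)
        qpcr_estimates = [estimate_copy_number(m) for m in measurements]
        qpcr_verdicts = concordance(qpcr_estimates)
        with open(out / "qpcr_copy_number.tsv", "w") as fh:
            fh.write("sample\tassay\tdelta_ct\tcopy_number\tsd\treliable\tverdict\n")
            for e in qpcr_estimates:
                key = (e.measurement.sample_id, e.measurement.assay_id)
                fh.write(
                    f"{key[0]}\t{key[1]}\t{e.delta_ct:.4f}\t{e.copy_number:.4f}\t"
                    f"{e.sd:.4f}\t{int(e.reliable)}\t"
                    f"{qpcr_verdicts.get(key, '')}\n"
                )
        counts["qpcr_measurements"] = len(qpcr_estimates)

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "distance_metric": cfg.distance_metric,
        "counts": counts,
        "versions": _lib_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        config=cfg,
        build=build,
        sheet=sheet,
        calls_by_tool=calls_by_tool,
        filtered_by_tool=filtered_by_tool,
        union_loci=loci,
        matrix=matrix,
        mds=mds,
        tree=tree,
        extreme_exonic=extreme_exonic,
        tool_cnvrs=tool_cnvrs,
        consensus=consensus,
        shared_all_breeds=shared_all,
        shared_by_region=shared_by_region,
        exclusive_by_region=exclusive_by_region,
        summaries=summaries,
        qtl_enrichment=qtl_enrichment,
        ora=ora,
        qpcr_estimates=qpcr_estimates,
        qpcr_verdicts=qpcr_verdicts,
        genes=genes,
        qtl=qtl,
        manifest=manifest,
        out_dir=out,
    )


def _lib_versions() -> dict[str, str]:
    import numpy, pandas, scipy  # noqa: E401

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
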