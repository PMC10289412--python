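"""End-to-end orchestration: annotate -> quantify -> diff-re -> scan ->
mre-expr -> diff-mre -> integrate, from one validated config.

Every stage writes a provenance-stamped TSV (tool version, config hash and
the thresholds in force) so a run can be audited from its outputs alone;
identical config + inputs give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from . import annotation_io, mre_quant, mre_scan, re_quant, target_integration

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "write_table", "read_table"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds for one pipeline run."""

    repeats: str
    repeat_dialect: str = "rm_out"
    genes: str = ""
    genome: str = ""
    mirnas: str = ""
    species_prefix: str = ""
    # either per-sample alignments, or a precomputed count table + totals
    alignments: dict = field(default_factory=dict)  # sample_id -> SAM/BAM path
    counts: str = ""
    totals: str = ""
    groups: dict = field(default_factory=dict)  # sample_id -> {normal, tumor}
    keep_classes: tuple = ("LINE", "LTR")
    strand_mode: str = "same_strand"
    min_length_bp: int = 200
    min_rpkm: float = 1.0
    min_samples: int = 1
    alpha: float = 0.05
    fc_threshold: float = 1.0
    pseudocount: float = 0.25
    weighting_mode: str = "count_weighted"
    scan_scope: str = "significant"  # or "all": which loci to scan for MREs
    # optional integration inputs
    targets_8m: str = ""
    targets_7a1: str = ""
    targets_7m8: str = ""
    target_dbs: tuple = ()  # >= 2 database export files to intersect
    degs: str = ""
    deg_alpha: float = 0.05
    deg_fc_threshold: float = 1.0
    outdir: str = "retroce_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML/JSON mapping")
        for key in ("keep_classes", "target_dbs"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        required = [("repeats", self.repeats), ("genes", self.genes)]
        if not self.alignments and not self.counts:
            raise ValueError("config needs either per-sample alignments or a count table")
        if self.counts:
            required += [("counts", self.counts), ("totals", self.totals)]
        if self.genome or self.mirnas:
            required += [("genome", self.genome), ("mirnas", self.mirnas)]
        for name, p in required + [(f"alignments[{s}]", p) for s, p in self.alignments.items()]:
            if not p:
                raise ValueError(f"config field {name} is required but empty")
            if not Path(p).exists():
                raise FileNotFoundError(f"config field {name}: no such file {p}")
        if self.strand_mode not in {"same_strand", "any_strand"}:
            raise ValueError(f"strand_mode must be same_strand or any_strand, got {self.strand_mode!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.fc_threshold < 0 or self.min_rpkm < 0 or self.min_length_bp < 0:
            raise ValueError("thresholds must be >= 0")

    def hash(self) -> str:
        """Digest of the analytical parameters (the output location is not one)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object]) -> None:
    """Write a TSV with '#'-prefixed provenance header lines."""
    buf = io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, sep="\t")
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _load_groups(config: PipelineConfig, samples) -> dict[str, str]:
    if config.groups:
        return dict(config.groups)
    raise ValueError("config.groups is empty: map each sample_id to normal/tumor")


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the in-memory result bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"retroce {__version__}", "config_hash": config.hash()}
    results: dict = {"config": config}

    def stage(name):
        log.info("stage %s", name)
        return name

    # ---- annotate -----------------------------------------------------
    stage("annotate")
    all_loci = annotation_io.parse_repeatmasker(config.repeats, config.repeat_dialect)
    re_loci = annotation_io.filter_re_classes(all_loci, config.keep_classes)
    genes = annotation_io.parse_gene_bodies(config.genes)
    loci = annotation_io.subtract_gene_overlaps(re_loci, genes, config.strand_mode)
    log.info("annotate: %d repeats -> %d %s -> %d intergenic",
             len(all_loci), len(re_loci), "/".join(config.keep_classes), len(loci))
    annotation_io.write_bed(loci, outdir / "intergenic_loci.bed")
    results["loci"] = loci

    # ---- quantify -----------------------------------------------------
    stage("quantify")
    locus_ids = [l.locus_id for l in loci]
    if config.alignments:
        counts, totals = re_quant.count_matrix(config.alignments, loci)
    else:
        counts = read_table(config.counts)
        totals_df = pd.read_csv(config.totals, sep="\t", comment="#")
        totals = dict(zip(totals_df["sample_id"], totals_df["total_mapped_reads"]))
        counts = counts.loc[counts.index.intersection(locus_ids)]
    groups = _load_groups(config, counts.columns)
    libraries = [
        re_quant.SampleLibrary(s, groups[s], int(totals[s])) for s in counts.columns
    ]
    expr = re_quant.rpkm(counts, loci, libraries)
    thresholds = {
        "min_length_bp": config.min_length_bp, "min_rpkm": config.min_rpkm,
        "min_samples": config.min_samples, "alpha": config.alpha,
        "fc_threshold": config.fc_threshold, "pseudocount": config.pseudocount,
    }
    write_table(counts, outdir / "re_counts.tsv", meta)
    write_table(expr, outdir / "re_rpkm.tsv", meta)
    log.info("quantify: %d loci x %d samples", *expr.shape)

    # ---- diff-re ------------------------------------------------------
    stage("diff-re")
    expr_kept = re_quant.size_expression_filter(
        expr, loci, config.min_length_bp, config.min_rpkm, config.min_samples
    )
    diff_re = re_quant.differential_expression(
        expr_kept, groups, config.alpha, config.fc_threshold, config.pseudocount
    )
    write_table(diff_re, outdir / "diff_re.tsv", meta | thresholds)
    log.info("diff-re: %d/%d loci significant", int(diff_re["significant"].sum()), len(diff_re))
    results.update(counts=counts, rpkm=expr, rpkm_filtered=expr_kept, diff_re=diff_re)

    # ---- scan + mre-expr + diff-mre ----------------------------------
    if config.genome and config.mirnas:
        stage("scan")
        mirnas = mre_scan.parse_mirna_fasta(config.mirnas, config.species_prefix)
        families = mre_scan.collapse_families(mirnas)
        patterns = [fam["patterns"] for fam in families.values()]
        if config.scan_scope == "significant":
            scan_ids = set(diff_re.index[diff_re["significant"]])
        else:
            scan_ids = set(expr_kept.index)
        scan_loci_list = [l for l in loci if l.locus_id in scan_ids]
        seqs = mre_scan.extract_re_sequences(config.genome, scan_loci_list)
        sites = mre_scan.scan_loci(seqs, patterns)
        sites_df = mre_quant.sites_to_frame(sites)
        write_table(sites_df, outdir / "mre_sites.tsv", meta)
        log.info("scan: %d sites on %d loci (%d seed families)",
                 len(sites), len(scan_loci_list), len(families))

        stage("mre-expr")
        site_counts = mre_quant.site_count_table(sites_df)
        mre_expr = mre_quant.mre_expression(
            expr_kept.loc[expr_kept.index.intersection(scan_ids)], site_counts,
            mode=config.weighting_mode,
        )
        write_table(mre_expr, outdir / "mre_expression.tsv",
                    meta | {"weighting_mode": config.weighting_mode})
        results.update(sites=sites_df, mre_expression=mre_expr, families=families)

        stage("diff-mre")
        if len(mre_expr):
            diff_mre = mre_quant.differential_mre(
                mre_expr, groups, config.alpha, config.fc_threshold, config.pseudocount
            )
            proportions = mre_quant.type_proportions(sites_df) if len(sites_df) else {}
        else:
            diff_mre = pd.DataFrame(
                columns=["mean_normal", "mean_tumor", "log2fc", "p_value", "significant"]
            )
            proportions = {}
        write_table(diff_mre, outdir / "diff_mre.tsv", meta | thresholds)
        with open(outdir / "mre_type_proportions.json", "w") as fh:
            json.dump(proportions, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("diff-mre: %d/%d MREs significant",
                 int(diff_mre["significant"].sum()) if len(diff_mre) else 0, len(diff_mre))
        results.update(diff_mre=diff_mre, type_proportions=proportions)

    # ---- integrate ----------------------------------------------------
    if config.targets_8m and config.targets_7a1 and config.targets_7m8:
        stage("integrate")
        by_type = {
            "8M": target_integration.read_gene_list(config.targets_8m, "8M"),
            "7A1": target_integration.read_gene_list(config.targets_7a1, "7A1"),
            "7M8": target_integration.read_gene_list(config.targets_7m8, "7M8"),
        }
        common, venn = target_integration.common_across_types(by_type)
        final = common
        if config.degs:
            degs = pd.read_csv(config.degs, sep="\t", comment="#")
            degs = target_integration.classify_degs(degs, config.deg_alpha, config.deg_fc_threshold)
            final = target_integration.remove_downregulated(common, degs)
        if len(config.target_dbs) >= 2:
            db_sets = [target_integration.read_gene_list(p) for p in config.target_dbs]
            db_common = target_integration.intersect_targets(db_sets)
            results["db_common_targets"] = db_common
            (outdir / "db_common_targets.txt").write_text(
                "\n".join(sorted(db_common.genes)) + "\n"
            )
        (outdir / "released_genes.txt").write_text("\n".join(sorted(final.genes)) + "\n")
        with open(outdir / "venn_counts.json", "w") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("integrate: %d common across types -> %d after removing down-regulated",
                 len(common), len(final))
        results.update(common_targets=common, venn=venn, released_genes=final)

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(
            {"tool": f"retroce {__version__}", "config_hash": config.hash(),
             "config": dataclasses.asdict(config)},
            fh, indent=2, sort_keys=True, default=str,
        )
        fh.write("\n")
    return results
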