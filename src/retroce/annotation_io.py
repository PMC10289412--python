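"""Repeat and gene annotation ingestion, and the intergenic-RE filter.

Repeat loci come from RepeatMasker output (either the classic ``.out``
fixed-column text or a UCSC rmsk-style table); gene bodies come from a
GTF/GFF3 annotation.  Everything is converted to 0-based half-open
coordinates on ingest so that downstream interval arithmetic has a single
convention.  The intergenic filter removes every retroelement locus that
overlaps a gene body by at least one base pair, mirroring the semantics of
``bedtools intersect -s -v`` (strand-matched, whole-feature removal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pyranges as pr

log = logging.getLogger(__name__)

__all__ = [
    "RELocus",
    "GeneInterval",
    "parse_repeatmasker",
    "filter_re_classes",
    "parse_gene_bodies",
    "subtract_gene_overlaps",
    "write_bed",
    "read_bed",
    "loci_to_frame",
    "class_family_summary",
]

#: rmsk-style table columns used when the file carries no header (UCSC dump order).
_RMSK_COLUMNS = [
    "bin", "swScore", "milliDiv", "milliDel", "milliIns",
    "genoName", "genoStart", "genoEnd", "genoLeft", "strand",
    "repName", "repClass", "repFamily",
]


@dataclass(frozen=True)
class RELocus:
    """A retroelement annotation interval, the unit of quantification.

    Coordinates are 0-based half-open.  ``locus_id`` is ``chrom:start:strand``
    and must be unique within a locus set.
    """

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str = "."
    rep_class: str = "."
    rep_family: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"locus {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"locus {self.chrom}:{self.start}: strand must be + or -, got {self.strand!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}:{self.strand}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneInterval:
    """A gene body span (full gene extent, not exon-resolved), 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")


def _split_class_family(repclass_field: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family field; class-only entries reuse the class."""
    if "/" in repclass_field:
        cls, fam = repclass_field.split("/", 1)
        return cls, fam
    return repclass_field, repclass_field


def _parse_rm_out(path: Path) -> list[RELocus]:
    loci: list[RELocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue  # 2 header lines + 1 blank separator
            fields = line.split()
            if len(fields) < 14:
                raise ValueError(f"{path}: malformed RepeatMasker .out row at line {lineno}")
            try:
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer coordinates at line {lineno}") from exc
            strand = "-" if fields[8] == "C" else fields[8]
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}: bad strand {fields[8]!r} at line {lineno}")
            cls, fam = _split_class_family(fields[10])
            # .out coordinates are 1-based inclusive
            loci.append(RELocus(fields[4], begin - 1, end, strand, fields[9], cls, fam))
    return loci


def _parse_rmsk_table(path: Path) -> list[RELocus]:
    with open(path) as fh:
        first = fh.readline()
    has_header = "genoName" in first
    if has_header:
        df = pd.read_csv(path, sep="\t")
    else:
        ncol = len(first.rstrip("\n").split("\t"))
        if ncol < len(_RMSK_COLUMNS):
            raise ValueError(
                f"{path}: rmsk table needs >= {len(_RMSK_COLUMNS)} columns or a header, got {ncol}"
            )
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = _RMSK_COLUMNS + [f"extra{i}" for i in range(ncol - len(_RMSK_COLUMNS))]
    required = {"genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: rmsk table missing columns {sorted(missing)}")
    loci = []
    for row in df.itertuples(index=False):
        strand = "-" if row.strand == "C" else row.strand
        # table coordinates are already 0-based half-open
        loci.append(
            RELocus(str(row.genoName), int(row.genoStart), int(row.genoEnd), strand,
                    str(row.repName), str(row.repClass), str(row.repFamily))
        )
    return loci


def parse_repeatmasker(path: str | Path, dialect: str = "rm_out") -> list[RELocus]:
    """Parse a repeat annotation into a list of :class:`RELocus`.

    Parameters
    ----------
    path
        RepeatMasker ``.out`` file or rmsk-style tab-separated table.
    dialect
        ``"rm_out"`` for the fixed-column ``.out`` text (1-based inclusive,
        strand ``C`` meaning minus) or ``"rmsk"`` / ``"rmsk_table"`` for the
        half-open table dump.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "rm_out":
        return _parse_rm_out(path)
    if dialect in {"rmsk", "rmsk_table"}:
        return _parse_rmsk_table(path)
    raise ValueError(f"unknown repeat dialect {dialect!r}; expected rm_out or rmsk_table")


def filter_re_classes(loci: Sequence[RELocus], keep: Iterable[str]) -> list[RELocus]:
    """Order-preserving subset of loci whose repeat class is in ``keep``."""
    keep = set(keep)
    if not keep:
        raise ValueError("keep must name at least one repeat class")
    return [l for l in loci if l.rep_class in keep]


def parse_gene_bodies(path: str | Path) -> list[GeneInterval]:
    """Extract one full-span gene-body interval per gene from a GTF/GFF3 file.

    ``gene`` features are used where present; genes represented only by
    transcripts (or other sub-features carrying ``gene_id``) get the min-start /
    max-end span over those features.  GTF/GFF 1-based inclusive coordinates are
    converted to 0-based half-open.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict[str, GeneInterval] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        genes[gid] = GeneInterval(gid, g.seqid, g.start - 1, g.end, g.strand)
    # genes lacking an explicit gene feature: span union over their features
    spans: dict[str, list] = {}
    for feat in db.all_features():
        if feat.featuretype == "gene":
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None or gid in genes:
            continue
        rec = spans.setdefault(gid, [feat.seqid, feat.start, feat.end, feat.strand])
        rec[1] = min(rec[1], feat.start)
        rec[2] = max(rec[2], feat.end)
    for gid, (chrom, start, end, strand) in spans.items():
        genes[gid] = GeneInterval(gid, chrom, start - 1, end, strand)
    if not genes:
        raise ValueError(f"{path}: no gene features (and none derivable from gene_id attributes)")
    return list(genes.values())


def subtract_gene_overlaps(
    re_loci: Sequence[RELocus],
    genes: Sequence[GeneInterval],
    strand_mode: str = "same_strand",
) -> list[RELocus]:
    """Remove every RE locus overlapping a gene body by >= 1 bp.

    ``same_strand`` only removes loci overlapping a gene on the same strand
    (bedtools ``intersect -s -v`` semantics); ``any_strand`` removes on
    overlap regardless of strand.  Loci are removed whole, never truncated.
    """
    if strand_mode not in {"same_strand", "any_strand"}:
        raise ValueError(f"unknown strand_mode {strand_mode!r}; expected same_strand or any_strand")
    if not re_loci:
        return []
    if not genes:
        return list(re_loci)
    re_df = pd.DataFrame(
        {
            "Chromosome": [l.chrom for l in re_loci],
            "Start": [l.start for l in re_loci],
            "End": [l.end for l in re_loci],
            "Strand": [l.strand for l in re_loci],
            "idx": range(len(re_loci)),
        }
    )
    gene_df = pd.DataFrame(
        {
            "Chromosome": [g.chrom for g in genes],
            "Start": [g.start for g in genes],
            "End": [g.end for g in genes],
            "Strand": [g.strand for g in genes],
        }
    )
    strandedness = "same" if strand_mode == "same_strand" else None
    surviving = pr.PyRanges(re_df).overlap(pr.PyRanges(gene_df), strandedness=strandedness, invert=True)
    kept = set(surviving.df["idx"]) if len(surviving) else set()
    out = [l for i, l in enumerate(re_loci) if i in kept]
    log.info("intergenic filter (%s): %d/%d loci retained", strand_mode, len(out), len(re_loci))
    return out


def write_bed(loci: Sequence[RELocus], path: str | Path) -> None:
    """Write loci as BED6 (name = locus_id, score = 0)."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t0\t{l.strand}\n")


def read_bed(path: str | Path) -> list[RELocus]:
    """Read a BED6 file back into RELocus records (repeat name/class unknown)."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: BED6 row with <6 columns at line {lineno}")
            loci.append(RELocus(fields[0], int(fields[1]), int(fields[2]), fields[5]))
    return loci


def loci_to_frame(loci: Sequence[RELocus]) -> pd.DataFrame:
    """Tabular view of a locus list, indexed by locus_id."""
    df = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "strand": [l.strand for l in loci],
            "rep_name": [l.rep_name for l in loci],
            "rep_class": [l.rep_class for l in loci],
            "rep_family": [l.rep_family for l in loci],
        }
    )
    return df.set_index("locus_id")


def class_family_summary(loci: Sequence[RELocus]) -> pd.DataFrame:
    """Locus tallies per (rep_class, rep_family), descending."""
    df = loci_to_frame(loci)
    out = df.groupby(["rep_class", "rep_family"]).size().rename("n_loci").reset_index()
    return out.sort_values(["rep_class", "n_loci"], ascending=[True, False]).reset_index(drop=True)
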