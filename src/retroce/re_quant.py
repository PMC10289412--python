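"""Read counting over RE loci, RPKM normalization and differential expression.

Counting follows the contract of ``bedtools multicov -s -f 1``: an alignment
is attributed to a locus only when its reference span is fully contained in
the locus interval and its strand matches the locus strand.  No MAPQ or
duplicate filtering is applied and multi-mapped records count at every
reported alignment, as the underlying command would.  Counts are normalized
to RPKM (count x 1e9 / (length_bp x total_mapped_reads)) and two-group
differences are screened with Welch's t-test on log2(RPKM + pseudocount).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .annotation_io import RELocus

log = logging.getLogger(__name__)

__all__ = [
    "SampleLibrary",
    "count_reads",
    "count_matrix",
    "rpkm",
    "size_expression_filter",
    "differential_expression",
]


@dataclass(frozen=True)
class SampleLibrary:
    """Per-sample library metadata: group label and sequencing depth."""

    sample_id: str
    group: str
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError(f"sample {self.sample_id}: total_mapped_reads must be > 0")


def count_reads(alignment_file: str | Path, loci: Sequence[RELocus]) -> tuple[pd.Series, int]:
    """Count strand-matched, fully-contained alignments per locus.

    Returns the per-locus count column (indexed by locus_id) and the total
    number of mapped records in the file.  An alignment can count toward
    several nested/containing loci; unmapped records are skipped but do not
    stop iteration.
    """
    alignment_file = Path(alignment_file)
    if not alignment_file.exists():
        raise FileNotFoundError(alignment_file)
    # per-chromosome arrays for vectorized containment tests
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {l.chrom for l in loci}:
        sub = [(i, l) for i, l in enumerate(loci) if l.chrom == chrom]
        idx = np.array([i for i, _ in sub])
        starts = np.array([l.start for _, l in sub])
        ends = np.array([l.end for _, l in sub])
        minus = np.array([l.strand == "-" for _, l in sub])
        by_chrom[chrom] = (idx, starts, ends, minus)
    counts = np.zeros(len(loci), dtype=np.int64)
    total_mapped = 0
    seen_chrom_match = False
    mode = "rb" if alignment_file.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(alignment_file), mode) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            total_mapped += 1
            chrom = rec.reference_name
            entry = by_chrom.get(chrom)
            if entry is None:
                continue
            seen_chrom_match = True
            idx, starts, ends, minus = entry
            hit = (starts <= rec.reference_start) & (ends >= rec.reference_end) & (minus == rec.is_reverse)
            counts[idx[hit]] += 1
    if total_mapped and not seen_chrom_match:
        log.warning(
            "%s: no mapped record landed on a chromosome carrying loci "
            "(chromosome-name mismatch?)", alignment_file,
        )
    return pd.Series(counts, index=[l.locus_id for l in loci], name="count"), total_mapped


def count_matrix(
    alignment_files: Mapping[str, str | Path], loci: Sequence[RELocus]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count every sample's alignment file; returns (loci x samples, totals)."""
    columns, totals = {}, {}
    for sample_id, path in alignment_files.items():
        col, total = count_reads(path, loci)
        columns[sample_id] = col
        totals[sample_id] = total
        log.info("%s: %d mapped records, %d counted on loci", sample_id, total, int(col.sum()))
    return pd.DataFrame(columns), totals


def rpkm(
    counts: pd.DataFrame, loci: Sequence[RELocus], libraries: Sequence[SampleLibrary]
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads: count x 1e9 / (len x total)."""
    lengths = pd.Series({l.locus_id: l.length for l in loci}).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise KeyError(f"count matrix rows missing from loci: {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("zero-length locus in RPKM normalization")
    totals = pd.Series({lib.sample_id: lib.total_mapped_reads for lib in libraries})
    missing = [s for s in counts.columns if s not in totals.index]
    if missing:
        raise KeyError(f"samples without total_mapped_reads: {missing}")
    out = counts.astype(float) * 1e9
    out = out.div(lengths, axis=0).div(totals.reindex(counts.columns), axis=1)
    return out


def size_expression_filter(
    expr: pd.DataFrame,
    loci: Sequence[RELocus],
    min_length_bp: int = 200,
    min_rpkm: float = 1.0,
    min_samples: int = 1,
) -> pd.DataFrame:
    """Keep loci with length >= min_length_bp and RPKM >= min_rpkm in >= min_samples samples."""
    if min(min_length_bp, min_rpkm, min_samples) < 0:
        raise ValueError("filter thresholds must be >= 0")
    lengths = pd.Series({l.locus_id: l.length for l in loci}).reindex(expr.index)
    long_enough = lengths >= min_length_bp
    expressed = (expr >= min_rpkm).sum(axis=1) >= min_samples
    kept = expr.loc[long_enough & expressed]
    log.info(
        "size/expression filter (len>=%d, rpkm>=%g in >=%d): %d/%d loci retained",
        min_length_bp, min_rpkm, min_samples, len(kept), len(expr),
    )
    return kept


def differential_expression(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
    pseudocount: float = 0.25,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Two-group differential screen on an expression matrix.

    ``log2fc = log2((mean_tumor + eps) / (mean_normal + eps))`` on the raw
    expression scale; the p-value is a two-sided Welch t-test on
    ``log2(expr + eps)``.  A feature is significant when ``p < alpha`` and
    ``|log2fc| > fc_threshold``.  The table is sorted by p ascending, ties by
    |log2fc| descending then feature id.  With ``bh_correction`` a
    Benjamini-Hochberg ``q_value`` column is added and used for the
    significance call in place of the raw p-value.
    """
    normal = [s for s in expr.columns if groups.get(s) == "normal"]
    tumor = [s for s in expr.columns if groups.get(s) == "tumor"]
    unknown = [s for s in expr.columns if s not in groups]
    if unknown:
        raise KeyError(f"samples without group labels: {unknown}")
    if len(normal) < 2 or len(tumor) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(normal)} normal / {len(tumor)} tumor"
        )
    eps = pseudocount
    mean_n = expr[normal].mean(axis=1)
    mean_t = expr[tumor].mean(axis=1)
    log2fc = np.log2((mean_t + eps) / (mean_n + eps))
    log_expr = np.log2(expr + eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(
            log_expr[tumor], log_expr[normal], axis=1, equal_var=False
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero variance, equal means
    table = pd.DataFrame(
        {
            "mean_normal": mean_n,
            "mean_tumor": mean_t,
            "log2fc": log2fc,
            "p_value": pvals,
        },
        index=expr.index,
    )
    crit = table["p_value"].to_numpy()
    if bh_correction:
        table["q_value"] = _benjamini_hochberg(table["p_value"].to_numpy())
        crit = table["q_value"].to_numpy()
    table["significant"] = (crit < alpha) & (table["log2fc"].abs() > fc_threshold)
    table = table.reset_index(names="feature")
    table["_absfc"] = table["log2fc"].abs()
    table = table.sort_values(
        ["p_value", "_absfc", "feature"], ascending=[True, False, True]
    ).drop(columns="_absfc")
    return table.set_index("feature")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out
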