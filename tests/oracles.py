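"""Independent brute-force referees used by the test suite.

These deliberately take a different route from the package: the site oracle
enumerates every sequence window instead of substring-searching patterns;
the overlap and containment oracles are all-pairs loops; Welch's statistic
is evaluated from its textbook formula.
"""

from __future__ import annotations

import math

import pysam
from scipy import stats


def oracle_scan(seq: str, patterns) -> set[tuple[str, str, int]]:
    """Enumerate all 7/8-mer windows, classify, apply 8M > 7M8 > 7A1 precedence."""
    win7: dict[str, list[int]] = {}
    win8: dict[str, list[int]] = {}
    for i in range(len(seq) - 6):
        win7.setdefault(seq[i : i + 7], []).append(i)
    for i in range(len(seq) - 7):
        win8.setdefault(seq[i : i + 8], []).append(i)
    out: set[tuple[str, str, int]] = set()
    for pat in patterns:
        p8 = set(win8.get(pat.site_8m, []))
        out |= {(pat.family_key, "8M", i) for i in p8}
        out |= {(pat.family_key, "7M8", i) for i in win7.get(pat.site_7m8, []) if i not in p8}
        out |= {(pat.family_key, "7A1", i) for i in win7.get(pat.site_7a1, []) if i - 1 not in p8}
    return out


def oracle_count_sam(path, loci) -> dict[str, int]:
    """Per-read, per-locus containment + strand loop over a SAM file."""
    counts = {l.locus_id: 0 for l in loci}
    with pysam.AlignmentFile(str(path), "r") as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            for l in loci:
                if (
                    l.chrom == rec.reference_name
                    and l.start <= rec.reference_start
                    and rec.reference_end <= l.end
                    and l.strand == strand
                ):
                    counts[l.locus_id] += 1
    return counts


def overlapping_pairs(loci, genes, same_strand_only: bool) -> list[tuple[str, str]]:
    """All-pairs >=1 bp interval-overlap check."""
    out = []
    for l in loci:
        for g in genes:
            if l.chrom != g.chrom:
                continue
            if same_strand_only and l.strand != g.strand:
                continue
            if max(l.start, g.start) < min(l.end, g.end):
                out.append((l.locus_id, g.gene_id))
    return out


def welch_p(a, b) -> float:
    """Two-sided Welch t-test from the textbook formula."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)
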