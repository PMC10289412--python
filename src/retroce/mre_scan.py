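"""miRNA seed-site patterns and the MRE scanner.

A miRNA recognises targets chiefly through its seed (nucleotides 2-7,
extended to 8 for the stronger site classes).  Three canonical site types
are searched on the sense sequence of each RE transcript:

* ``8M``  - perfect Watson-Crick match to miRNA positions 2-8 plus a
  target adenosine opposite position 1,
* ``7M8`` - match to positions 2-8 only,
* ``7A1`` - match to positions 2-7 plus the position-1 adenosine.

The appended ``A`` of 8M/7A1 is a literal target adenosine, not
complementarity to miRNA position 1.  Because the 7M8 string is a prefix of
the 8M string and the 7A1 string is its suffix, every 8M occurrence textually
implies one of each; the scanner therefore applies a precedence rule
(8M > 7M8 > 7A1 at subsumed windows) so a physical site is reported exactly
once.  miRNAs sharing positions 2-8 are collapsed into one seed family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .annotation_io import RELocus

__all__ = [
    "MatureMiRNA",
    "SeedPatterns",
    "MRESite",
    "SITE_TYPES",
    "parse_mirna_fasta",
    "seed_patterns",
    "collapse_families",
    "family_label",
    "extract_re_sequences",
    "scan_sites",
    "scan_loci",
]

SITE_TYPES = ("8M", "7M8", "7A1")

_VALID_RNA = re.compile(r"^[ACGU]+$")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: name, 5'->3' RNA sequence, and its species prefix."""

    name: str
    sequence: str
    species_prefix: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(f"{self.name}: mature miRNA must be >= 8 nt, got {len(self.sequence)}")
        if not _VALID_RNA.match(self.sequence):
            raise ValueError(f"{self.name}: sequence must be RNA alphabet ACGU")


@dataclass(frozen=True)
class SeedPatterns:
    """DNA site strings for the three binding types of one miRNA.

    ``family_key`` is the DNA transliteration of miRNA positions 2-8 and is
    shared by all members of a seed family.
    """

    mirna_name: str
    family_key: str
    site_8m: str
    site_7m8: str
    site_7a1: str

    def __post_init__(self) -> None:
        assert len(self.site_8m) == 8 and len(self.site_7m8) == 7 and len(self.site_7a1) == 7
        assert self.site_8m.startswith(self.site_7m8)
        assert self.site_8m[1:] == self.site_7a1

    def by_type(self) -> dict[str, str]:
        return {"8M": self.site_8m, "7M8": self.site_7m8, "7A1": self.site_7a1}


@dataclass(frozen=True)
class MRESite:
    """A detected miRNA responsive element on one RE sequence."""

    locus_id: str
    mirna_family: str
    site_type: str
    offset: int


def parse_mirna_fasta(path: str | Path, species_prefix: str) -> list[MatureMiRNA]:
    """Read a miRBase-style mature FASTA, keeping one species.

    Names are the first whitespace token of each header; sequences are
    uppercased and normalised to the RNA alphabet (T -> U).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name.startswith(species_prefix):
            continue
        seq = str(rec.seq).upper().replace("T", "U")
        out.append(MatureMiRNA(name, seq, species_prefix))
    if not out:
        raise ValueError(f"{path}: no miRNA records with species prefix {species_prefix!r}")
    return out


def _rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def seed_patterns(mirna: MatureMiRNA) -> SeedPatterns:
    """Derive the three target-site strings from miRNA positions 1-8.

    The 7M8 site is the reverse complement of positions 2-8; appending the
    literal target adenosine gives the 8M site, and dropping the base paired
    to position 8 from the 8M site gives the 7A1 site.
    """
    m2_8 = _rna_to_dna(mirna.sequence[1:8])
    m2_7 = _rna_to_dna(mirna.sequence[1:7])
    site_7m8 = str(Seq(m2_8).reverse_complement())
    site_7a1 = str(Seq(m2_7).reverse_complement()) + "A"
    return SeedPatterns(
        mirna_name=mirna.name,
        family_key=m2_8,
        site_8m=site_7m8 + "A",
        site_7m8=site_7m8,
        site_7a1=site_7a1,
    )


_SUFFIX_ARM = re.compile(r"-[35]p$")
_SUFFIX_LETTER = re.compile(r"(?<=\d)[a-z]+(-\d+)?$")


def family_label(member_names: Sequence[str]) -> str:
    """Display label for a seed family: first member, arm/letter suffix trimmed.

    ``hsa-let-7a-5p`` -> ``hsa-let-7``; ``hsa-miR-30c-2`` -> ``hsa-miR-30``.
    """
    name = sorted(member_names)[0]
    name = _SUFFIX_ARM.sub("", name)
    name = _SUFFIX_LETTER.sub("", name)
    return name


def collapse_families(mirnas: Sequence[MatureMiRNA]) -> dict[str, dict]:
    """Group miRNAs sharing positions 2-8 into seed families.

    Returns ``family_key -> {"label": str, "members": [names], "patterns": SeedPatterns}``.
    Site patterns are identical within a family by construction.
    """
    if not mirnas:
        raise ValueError("no miRNAs to collapse")
    families: dict[str, dict] = {}
    for m in mirnas:
        pat = seed_patterns(m)
        fam = families.setdefault(pat.family_key, {"members": [], "patterns": pat})
        fam["members"].append(m.name)
    for fam in families.values():
        fam["members"].sort()
        fam["label"] = family_label(fam["members"])
    return families


def extract_re_sequences(
    genome_fasta: str | Path, loci: Sequence[RELocus]
) -> dict[str, str]:
    """Extract each locus' transcript-sense sequence from the genome.

    Minus-strand loci are reverse-complemented (``bedtools getfasta -s``);
    the mapping is keyed by locus_id (``-name``).  Soft-masked lowercase is
    uppercased.
    """
    import pysam

    out: dict[str, str] = {}
    with pysam.FastaFile(str(genome_fasta)) as fa:
        lengths = dict(zip(fa.references, fa.lengths))
        for l in loci:
            if l.chrom not in lengths:
                raise KeyError(f"locus {l.locus_id}: chromosome {l.chrom} absent from {genome_fasta}")
            if l.end > lengths[l.chrom]:
                raise ValueError(
                    f"locus {l.locus_id} extends past end of {l.chrom} ({lengths[l.chrom]} bp)"
                )
            seq = fa.fetch(l.chrom, l.start, l.end).upper()
            if l.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            out[l.locus_id] = seq
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


_TYPE_ORDER = {t: i for i, t in enumerate(SITE_TYPES)}


def scan_sites(
    sequence: str,
    patterns: Sequence[SeedPatterns],
    locus_id: str = "",
) -> list[MRESite]:
    """Scan one uppercase DNA sequence for MREs of every given seed family.

    Each pattern occurrence is reported with precedence de-duplication: an 8M
    match suppresses the 7M8 it starts with and the 7A1 it ends with, so the
    three classes partition physical sites.  Ambiguity codes (N etc.) never
    match.  Output is sorted by (offset, family, type) and is independent of
    the order of ``patterns``.
    """
    sites: list[MRESite] = []
    seen_keys = set()
    for pat in patterns:
        if pat.family_key in seen_keys:
            continue  # duplicate family in the pattern list
        seen_keys.add(pat.family_key)
        starts_8m = set(_find_all(sequence, pat.site_8m))
        for o in starts_8m:
            sites.append(MRESite(locus_id, pat.family_key, "8M", o))
        for o in _find_all(sequence, pat.site_7m8):
            if o not in starts_8m:
                sites.append(MRESite(locus_id, pat.family_key, "7M8", o))
        for o in _find_all(sequence, pat.site_7a1):
            if (o - 1) not in starts_8m:
                sites.append(MRESite(locus_id, pat.family_key, "7A1", o))
    sites.sort(key=lambda s: (s.offset, s.mirna_family, _TYPE_ORDER[s.site_type]))
    return sites


def scan_loci(
    sequences: Mapping[str, str], patterns: Sequence[SeedPatterns]
) -> list[MRESite]:
    """Scan every locus sequence; locus order follows the mapping order."""
    out: list[MRESite] = []
    for locus_id, seq in sequences.items():
        out.extend(scan_sites(seq, patterns, locus_id=locus_id))
    return out
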