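"""Fully specified synthetic corpus generator with a ground-truth manifest.

Every pipeline stage gets an oracle: a small random genome carries planted
retroelement loci of known class/family/strand, a configurable fraction of
which overlap genes on the same or the opposite strand (to exercise the
intergenic filter); locus sequences carry exactly known numbers of planted
miRNA seed sites per binding type (rejection sampling removes accidental
matches of every tracked family); two-group expression follows a log-normal
baseline with planted fold changes, realised as Poisson read counts and,
optionally, as minimal single-end SAM records with deliberately labelled
straddling and antisense reads that a correct counter must ignore.

The manifest alone predicts the exact output of intergenic filtering, read
counting, site scanning, type proportions and target filtering, which makes
it the referee for every recovery test.  The default configuration is the
study design the generator emulates at desk scale: a 5-vs-5 two-group
comparison with 4-fold (log2FC = 2) planted effects on 10% of loci and
log-normal expression noise of 0.3 on the log2 scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation_io import RELocus
from .mre_scan import MatureMiRNA, SeedPatterns, collapse_families, seed_patterns

__all__ = [
    "SyntheticConfig",
    "GroundTruthManifest",
    "random_mirnas",
    "plant_mre_sites",
    "simulate_genome_and_annotations",
    "simulate_counts",
    "simulate_count_study",
    "simulate_sam_corpus",
    "write_labeled_sam",
    "simulate_target_fixtures",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_FAMILIES = {"LINE": ["L1", "L2", "CR1"], "LTR": ["ERV1", "ERVL", "ERVL-MaLR"]}


@dataclass
class SyntheticConfig:
    """Generator knobs; the defaults are the emulated study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 60_000
    n_re_loci: int = 40
    re_length_range_bp: tuple[int, int] = (300, 800)
    n_genes: int = 6  # standalone intergenic genes, besides overlap genes
    fraction_re_overlapping_gene_same_strand: float = 0.2
    fraction_re_overlapping_gene_opposite_strand: float = 0.1
    n_mirnas: int = 5
    planted_sites_per_type: dict = field(default_factory=lambda: {"8M": 2, "7M8": 2, "7A1": 2})
    n_decoy_loci_per_family: int = 2
    n_normal: int = 5
    n_tumor: int = 5
    baseline_log2_rpkm_mean: float = 5.0
    baseline_log2_rpkm_sd: float = 1.0
    noise_log2_sd: float = 0.3
    planted_log2fc: float = 2.0
    fraction_diff: float = 0.1
    reads_per_sample: int = 2_000_000
    read_length: int = 50
    straddler_fraction: float = 0.2
    antisense_fraction: float = 0.1

    def validate(self) -> None:
        if min(self.n_chroms, self.n_re_loci, self.n_normal, self.n_tumor) < 0:
            raise ValueError("counts must be >= 0")
        for frac in (
            self.fraction_re_overlapping_gene_same_strand,
            self.fraction_re_overlapping_gene_opposite_strand,
            self.fraction_diff,
            self.straddler_fraction,
            self.antisense_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not np.isfinite(self.planted_log2fc):
            raise ValueError("planted_log2fc must be finite")
        if self.re_length_range_bp[0] < 20:
            raise ValueError("RE loci must be at least 20 bp to host sites")


class GroundTruthManifest:
    """Machine-readable ledger of everything the generator planted."""

    def __init__(self, data: dict):
        cfg = data.get("config", {})
        if "re_length_range_bp" in cfg:
            cfg["re_length_range_bp"] = list(cfg["re_length_range_bp"])  # JSON-stable
        self.data = data

    # -- accessors -------------------------------------------------------
    @property
    def loci(self) -> list[dict]:
        return self.data["loci"]

    @property
    def config(self) -> SyntheticConfig:
        cfg = dict(self.data["config"])
        cfg["re_length_range_bp"] = tuple(cfg["re_length_range_bp"])
        return SyntheticConfig(**cfg)

    @property
    def mirnas(self) -> list[MatureMiRNA]:
        return [MatureMiRNA(m["name"], m["sequence"]) for m in self.data["mirnas"]]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.data["chrom_lengths"]

    def re_loci(self) -> list[RELocus]:
        return [
            RELocus(l["chrom"], l["start"], l["end"], l["strand"],
                    l["rep_name"], l["rep_class"], l["rep_family"])
            for l in self.loci
        ]

    def intergenic_ids(self, strand_mode: str = "same_strand") -> set[str]:
        """Locus ids expected to survive the gene-overlap filter."""
        drop = {"same"} if strand_mode == "same_strand" else {"same", "opposite"}
        return {l["locus_id"] for l in self.loci if l["overlap"] not in drop}

    def true_log2fc(self) -> pd.Series:
        return pd.Series({l["locus_id"]: l["true_log2fc"] for l in self.loci})

    def planted_site_counts(self) -> pd.DataFrame:
        """Long table (locus_id, family, site_type, n_sites) of planted sites."""
        rows = []
        for l in self.loci:
            for fam, per_type in l["planted_sites"].items():
                for site_type, offsets in per_type.items():
                    if offsets:
                        rows.append((l["locus_id"], fam, site_type, len(offsets)))
        return pd.DataFrame(rows, columns=["locus_id", "family", "site_type", "n_sites"])

    # -- (de)serialisation ----------------------------------------------
    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(json.load(fh))


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _enumerate_matches(seq: str, patterns: Sequence[SeedPatterns]) -> set[tuple[str, str, int]]:
    """Window-enumeration matcher with the 8M > 7M8 > 7A1 precedence rule.

    Built on a position index of all 7/8-mer windows, so it is an
    implementation-independent referee for the planting loop.
    """
    idx7: dict[str, list[int]] = {}
    idx8: dict[str, list[int]] = {}
    for i in range(len(seq) - 6):
        idx7.setdefault(seq[i : i + 7], []).append(i)
    for i in range(len(seq) - 7):
        idx8.setdefault(seq[i : i + 8], []).append(i)
    out: set[tuple[str, str, int]] = set()
    for pat in patterns:
        p8 = set(idx8.get(pat.site_8m, []))
        out.update((pat.family_key, "8M", o) for o in p8)
        out.update(
            (pat.family_key, "7M8", o) for o in idx7.get(pat.site_7m8, []) if o not in p8
        )
        out.update(
            (pat.family_key, "7A1", o) for o in idx7.get(pat.site_7a1, []) if o - 1 not in p8
        )
    return out


def random_mirnas(rng: np.random.Generator, n: int, length: int = 21) -> list[MatureMiRNA]:
    """Random mature miRNAs with mutually non-confusable seed patterns.

    Regeneration guarantees that no family's 7-mer site string is a substring
    of another family's 8M site, so planted sites of one family can never
    create matches of another.
    """
    mirnas: list[MatureMiRNA] = []
    pats: list[SeedPatterns] = []
    attempts = 0
    while len(mirnas) < n:
        attempts += 1
        if attempts > 1000 * (n + 1):
            raise RuntimeError("could not generate non-confusable miRNA seeds")
        seq = "".join(rng.choice(["A", "C", "G", "U"], size=length))
        cand = MatureMiRNA(f"syn-miR-{len(mirnas) + 1}-5p", seq)
        cp = seed_patterns(cand)
        clash = False
        for other in pats:
            if cp.family_key == other.family_key:
                clash = True
                break
            for a, b in ((cp, other), (other, cp)):
                if a.site_7m8 in b.site_8m or a.site_7a1 in b.site_8m:
                    clash = True
            if clash:
                break
        if not clash:
            mirnas.append(cand)
            pats.append(cp)
    return mirnas


def plant_mre_sites(
    sequence: str,
    patterns: SeedPatterns,
    site_type: str,
    n: int,
    rng: np.random.Generator,
    tracked_patterns: Sequence[SeedPatterns] | None = None,
) -> tuple[str, list[int]]:
    """Plant exactly ``n`` sites of one type into a sequence.

    After stamping, the final sequence is guaranteed (by rejection sampling /
    local scrubbing) to contain exactly ``n`` detections of the requested
    (family, type) and zero detections of any other tracked pattern.
    """
    if tracked_patterns is None:
        tracked_patterns = [patterns]
    seq, planted = _plant_many(
        sequence, {(patterns.family_key, site_type): n},
        {patterns.family_key: patterns}, list(tracked_patterns), rng,
    )
    return seq, sorted(planted.get((patterns.family_key, site_type), []))


def _plant_many(
    sequence: str,
    wanted: Mapping[tuple[str, str], int],
    patterns_by_family: Mapping[str, SeedPatterns],
    tracked: Sequence[SeedPatterns],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[str, dict[tuple[str, str], list[int]]]:
    """Stamp a set of (family, type) -> n sites and scrub accidental matches."""
    site_len = {"8M": 8, "7M8": 7, "7A1": 7}
    total_span = sum(site_len[t] + 4 for (_, t), k in wanted.items() for _ in range(k))
    if total_span + 4 > len(sequence):
        raise ValueError(
            f"sequence of {len(sequence)} bp cannot host {sum(wanted.values())} non-overlapping sites"
        )
    base = sequence
    for attempt in range(max_tries):
        work = list(base)
        occupied: list[tuple[int, int]] = []  # padded windows, half-open
        planted: dict[tuple[str, str], list[int]] = {k: [] for k in wanted}
        expected: set[tuple[str, str, int]] = set()
        windows: list[tuple[int, int]] = []  # exact site windows (protected)
        ok = True
        for (family, site_type), k in wanted.items():
            pat = patterns_by_family[family].by_type()[site_type]
            for _ in range(k):
                placed = False
                for _try in range(200):
                    o = int(rng.integers(2, len(work) - len(pat) - 2))
                    lo, hi = o - 2, o + len(pat) + 2
                    if all(hi <= a or lo >= b for a, b in occupied):
                        occupied.append((lo, hi))
                        work[o : o + len(pat)] = pat
                        planted[(family, site_type)].append(o)
                        expected.add((family, site_type, o))
                        windows.append((o, o + len(pat)))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            base = _random_dna(rng, len(sequence))
            continue
        seq, clean = _scrub("".join(work), expected, windows, tracked, rng)
        if clean:
            return seq, planted
        base = _random_dna(rng, len(sequence))  # fresh background, retry
    raise RuntimeError(f"could not plant sites cleanly after {max_tries} attempts")


def _scrub(
    seq: str,
    expected: set[tuple[str, str, int]],
    protected: list[tuple[int, int]],
    tracked: Sequence[SeedPatterns],
    rng: np.random.Generator,
    rounds: int = 50,
) -> tuple[str, bool]:
    """Randomise bases of accidental matches outside protected windows."""
    site_len = {"8M": 8, "7M8": 7, "7A1": 7}
    for _ in range(rounds):
        found = _enumerate_matches(seq, tracked)
        if found == expected:
            return seq, True
        if expected - found:  # a planted site got clobbered: give up on this draw
            return seq, False
        work = list(seq)
        progress = False
        for family, site_type, o in sorted(found - expected):
            span = range(o, o + site_len[site_type])
            free = [i for i in span if not any(a <= i < b for a, b in protected)]
            if not free:
                return seq, False  # accidental match fully inside planted sites
            i = free[int(rng.integers(0, len(free)))]
            choices = [b for b in "ACGT" if b != work[i]]
            work[i] = choices[int(rng.integers(0, 3))]
            progress = True
        if not progress:
            return seq, False
        seq = "".join(work)
    return seq, _enumerate_matches(seq, tracked) == expected


# ---------------------------------------------------------------------------
# genome + annotations
# ---------------------------------------------------------------------------

def simulate_genome_and_annotations(
    config: SyntheticConfig, outdir: str | Path
) -> GroundTruthManifest:
    """Emit genome FASTA, repeat annotation (both dialects), gene GTF, miRNA
    FASTA and the JSON manifest.  Same config (incl. seed) => identical bytes.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    mirnas = random_mirnas(rng, config.n_mirnas)
    families = collapse_families(mirnas)
    fam_keys = sorted(families)
    patterns = [families[k]["patterns"] for k in fam_keys]
    target_family = fam_keys[0] if fam_keys else None

    chrom_names = [f"chrS{i + 1}" for i in range(config.n_chroms)]
    chroms = {c: list(_random_dna(rng, config.chrom_length_bp)) for c in chrom_names}
    reserve_start = int(config.chrom_length_bp * 0.85)

    # -- place locus coordinates ---------------------------------------
    lo_len, hi_len = config.re_length_range_bp
    cursors = {c: 0 for c in chrom_names}
    placements: list[tuple[str, int, int]] = []
    for i in range(config.n_re_loci):
        chrom = chrom_names[i % config.n_chroms]
        gap = int(rng.integers(160, 400))
        length = int(rng.integers(lo_len, hi_len + 1))
        start = cursors[chrom] + gap
        end = start + length
        if end + 160 > reserve_start:
            raise ValueError(
                f"cannot place {config.n_re_loci} loci of {lo_len}-{hi_len} bp "
                f"within {config.chrom_length_bp} bp chromosomes"
            )
        cursors[chrom] = end
        placements.append((chrom, start, end))

    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(config.n_re_loci)]
    classes, fams = [], []
    for _ in range(config.n_re_loci):
        cls = "LINE" if rng.random() < 0.5 else "LTR"
        classes.append(cls)
        fams.append(_FAMILIES[cls][int(rng.integers(0, len(_FAMILIES[cls])))])

    # -- overlap / differential / decoy role assignment ----------------
    n = config.n_re_loci
    k_same = round(config.fraction_re_overlapping_gene_same_strand * n)
    k_opp = round(config.fraction_re_overlapping_gene_opposite_strand * n)
    order = list(rng.permutation(n))
    same_ids = set(order[:k_same])
    opp_ids = set(order[k_same : k_same + k_opp])
    intergenic_pool = order[k_same + k_opp :]
    n_diff = round(config.fraction_diff * n)
    if n_diff > len(intergenic_pool):
        raise ValueError("fraction_diff exceeds the available intergenic loci")
    diff_ids = list(intergenic_pool[:n_diff])
    decoy_pool = list(intergenic_pool[n_diff:])
    decoy_assign: dict[int, str] = {}
    pos = 0
    for fam_key in fam_keys[1:]:
        for _ in range(config.n_decoy_loci_per_family):
            if pos < len(decoy_pool):
                decoy_assign[decoy_pool[pos]] = fam_key
                pos += 1

    # -- build locus sequences with planted sites -----------------------
    loci_records: list[dict] = []
    per_type = {t: int(c) for t, c in config.planted_sites_per_type.items() if c}
    for i, (chrom, start, end) in enumerate(placements):
        length = end - start
        wanted: dict[tuple[str, str], int] = {}
        if i in diff_ids and target_family is not None:
            wanted = {(target_family, t): c for t, c in per_type.items()}
        elif i in decoy_assign:
            wanted = {(decoy_assign[i], t): c for t, c in per_type.items()}
        seq = _random_dna(rng, length)
        if patterns:
            pats_by_fam = {p.family_key: p for p in patterns}
            seq, planted = _plant_many(seq, wanted, pats_by_fam, patterns, rng)
        else:
            planted = {}
        planted_sites = {
            fam: {t: sorted(offs) for (f2, t), offs in planted.items() if f2 == fam and offs}
            for fam in {f for (f, _t) in planted}
        }
        strand = strands[i]
        genomic = seq if strand == "+" else _revcomp(seq)
        chroms[chrom][start:end] = genomic
        overlap = "same" if i in same_ids else ("opposite" if i in opp_ids else "none")
        locus = RELocus(chrom, start, end, strand, f"{fams[i]}_syn{i + 1}", classes[i], fams[i])
        loci_records.append(
            {
                "locus_id": locus.locus_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "rep_name": locus.rep_name,
                "rep_class": classes[i],
                "rep_family": fams[i],
                "overlap": overlap,
                "true_log2fc": config.planted_log2fc if i in diff_ids else 0.0,
                "planted_sites": planted_sites,
            }
        )

    # -- genes: one per overlapped locus + standalone genes in reserve --
    genes: list[tuple[str, str, int, int, str]] = []  # gene_id, chrom, start, end(half-open), strand
    gid = 0
    for i, rec in enumerate(loci_records):
        if rec["overlap"] == "none":
            continue
        gid += 1
        g_start = max(0, rec["start"] - 150)
        g_end = rec["start"] + max(1, min(150, rec["end"] - rec["start"]))
        strand = rec["strand"] if rec["overlap"] == "same" else ("-" if rec["strand"] == "+" else "+")
        genes.append((f"SYNG{gid:04d}", rec["chrom"], g_start, g_end, strand))
    for j in range(config.n_genes):
        gid += 1
        chrom = chrom_names[j % config.n_chroms]
        g_len = int(rng.integers(400, 1200))
        g_start = reserve_start + 50 + (j // config.n_chroms) * 1500
        g_end = g_start + g_len
        if g_end > config.chrom_length_bp:
            raise ValueError("standalone genes do not fit in the gene reserve region")
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"SYNG{gid:04d}", chrom, g_start, g_end, strand))

    # -- write files -----------------------------------------------------
    _write_fasta(outdir / "genome.fa", {c: "".join(s) for c, s in chroms.items()})
    loci = [RELocus(r["chrom"], r["start"], r["end"], r["strand"],
                    r["rep_name"], r["rep_class"], r["rep_family"]) for r in loci_records]
    _write_rm_out(outdir / "repeats.out", loci, {c: len(s) for c, s in chroms.items()})
    _write_rmsk_table(outdir / "repeats.rmsk.tsv", loci)
    _write_gtf(outdir / "genes.gtf", genes)
    _write_mirna_fasta(outdir / "mirnas.fa", mirnas)

    manifest = GroundTruthManifest(
        {
            "config": asdict(config),
            "chrom_lengths": {c: len(s) for c, s in chroms.items()},
            "mirnas": [{"name": m.name, "sequence": m.sequence} for m in mirnas],
            "families": {
                k: {"label": families[k]["label"], "members": families[k]["members"]}
                for k in fam_keys
            },
            "target_family": target_family,
            "loci": loci_records,
            "genes": [
                {"gene_id": g, "chrom": c, "start": s, "end": e, "strand": st}
                for g, c, s, e, st in genes
            ],
        }
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _write_fasta(path: Path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    fai = Path(str(path) + ".fai")
    if fai.exists():
        fai.unlink()  # stale index from a previous corpus would poison fetches


def _write_rm_out(path: Path, loci: Sequence[RELocus], chrom_lengths: Mapping[str, int]) -> None:
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, l in enumerate(loci, start=1):
            left = chrom_lengths[l.chrom] - l.end
            strand = "+" if l.strand == "+" else "C"
            fh.write(
                f" 1500  10.0  0.5  0.5  {l.chrom} {l.start + 1} {l.end} ({left}) "
                f"{strand} {l.rep_name} {l.rep_class}/{l.rep_family} 1 {l.length} (0) {i}\n"
            )


def _write_rmsk_table(path: Path, loci: Sequence[RELocus]) -> None:
    rows = [
        {
            "bin": 0, "swScore": 1500, "milliDiv": 100, "milliDel": 5, "milliIns": 5,
            "genoName": l.chrom, "genoStart": l.start, "genoEnd": l.end, "genoLeft": 0,
            "strand": l.strand, "repName": l.rep_name, "repClass": l.rep_class,
            "repFamily": l.rep_family,
        }
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_gtf(path: Path, genes: Sequence[tuple[str, str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for gene_id, chrom, start, end, strand in genes:
            attrs = f'gene_id "{gene_id}";'
            fh.write(f"{chrom}\tsynthetic\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")
            fh.write(
                f"{chrom}\tsynthetic\ttranscript\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f'{attrs} transcript_id "{gene_id}.t1";\n'
            )


def _write_mirna_fasta(path: Path, mirnas: Sequence[MatureMiRNA]) -> None:
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.name} synthetic mature miRNA\n{m.sequence}\n")


# ---------------------------------------------------------------------------
# expression + reads
# ---------------------------------------------------------------------------

def _sample_ids(config: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    normal = [f"normal_{i + 1:02d}" for i in range(config.n_normal)]
    tumor = [f"tumor_{i + 1:02d}" for i in range(config.n_tumor)]
    groups = {s: "normal" for s in normal} | {s: "tumor" for s in tumor}
    return normal + tumor, groups


def simulate_counts(
    manifest: GroundTruthManifest, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, int], dict[str, str]]:
    """Two-group count table: log-normal RPKM baseline, Poisson realisation.

    Per locus, a baseline log2-RPKM is drawn once; tumour samples add the
    planted log2 fold change; every sample adds N(0, noise_log2_sd); counts
    are Poisson around ``rpkm * length * depth / 1e9``.
    """
    config = manifest.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    samples, groups = _sample_ids(config)
    loci = manifest.loci
    lengths = np.array([l["end"] - l["start"] for l in loci], dtype=float)
    fc = np.array([l["true_log2fc"] for l in loci])
    baseline = rng.normal(config.baseline_log2_rpkm_mean, config.baseline_log2_rpkm_sd, size=len(loci))
    counts = {}
    for s in samples:
        shift = fc if groups[s] == "tumor" else 0.0
        log2rpkm = baseline + shift + rng.normal(0.0, config.noise_log2_sd, size=len(loci))
        lam = (2.0 ** log2rpkm) * lengths * config.reads_per_sample / 1e9
        counts[s] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=[l["locus_id"] for l in loci])
    totals = {s: config.reads_per_sample for s in samples}
    return df, totals, groups


def simulate_count_study(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, int], dict[str, str], pd.Series, list[RELocus]]:
    """Count study without a genome: fabricated loci, planted fold changes.

    The generative model is the one used on the full corpus (log-normal
    baseline, planted log2FC on a ``fraction_diff`` subset, Poisson reads);
    only the sequence/annotation layers are skipped.  Returns counts, totals,
    group labels, the true per-locus log2FC, and the locus records.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.re_length_range_bp
    loci = []
    pos = 0
    for i in range(config.n_re_loci):
        length = int(rng.integers(lo, hi + 1))
        start = pos + 200
        loci.append(RELocus("chrS1", start, start + length, "+", f"L1_syn{i + 1}", "LINE", "L1"))
        pos = start + length
    n_diff = round(config.fraction_diff * config.n_re_loci)
    which = rng.permutation(config.n_re_loci)[:n_diff]
    truth = pd.Series(0.0, index=[l.locus_id for l in loci])
    truth.iloc[which] = config.planted_log2fc
    records = [
        {"locus_id": l.locus_id, "chrom": l.chrom, "start": l.start, "end": l.end,
         "strand": l.strand, "rep_name": l.rep_name, "rep_class": l.rep_class,
         "rep_family": l.rep_family, "overlap": "none",
         "true_log2fc": float(truth[l.locus_id]), "planted_sites": {}}
        for l in loci
    ]
    manifest = GroundTruthManifest(
        {"config": asdict(config), "chrom_lengths": {"chrS1": pos + 400},
         "mirnas": [], "families": {}, "target_family": None, "loci": records, "genes": []}
    )
    counts, totals, groups = simulate_counts(manifest, rng)
    return counts, totals, groups, truth, loci


def write_labeled_sam(
    path: str | Path,
    loci: Sequence[RELocus],
    chrom_lengths: Mapping[str, int],
    plan: Mapping[str, tuple[int, int, int]],
    read_length: int = 50,
    rng: np.random.Generator | None = None,
    n_unmapped: int = 2,
) -> dict[str, int]:
    """Write a minimal single-end SAM with labelled read categories per locus.

    ``plan[locus_id] = (n_contained, n_straddle, n_antisense)``.  Contained
    reads are strand-matched and fully inside the locus; straddlers extend
    past the locus end; antisense reads are contained on the wrong strand.
    Returns the expected per-locus counts (= n_contained) that a correct
    strand-matched full-containment counter must report.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in sorted(chrom_lengths.items())],
    }
    tid = {c: i for i, (c, _) in enumerate(sorted(chrom_lengths.items()))}
    expected: dict[str, int] = {}
    serial = 0

    def _segment(name, chrom, start, reverse):
        seg = pysam.AlignedSegment()
        seg.query_name = name
        seg.query_sequence = "A" * read_length
        seg.reference_id = tid[chrom]
        seg.reference_start = start
        seg.mapping_quality = 60
        seg.cigarstring = f"{read_length}M"
        seg.flag = 16 if reverse else 0
        return seg

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for locus in loci:
            n_cont, n_strad, n_anti = plan.get(locus.locus_id, (0, 0, 0))
            expected[locus.locus_id] = n_cont
            if locus.length < read_length:
                raise ValueError(f"{locus.locus_id}: locus shorter than read length")
            hi = locus.end - read_length
            rev = locus.strand == "-"
            for _ in range(n_cont):
                serial += 1
                start = int(rng.integers(locus.start, hi + 1))
                out.write(_segment(f"cont{serial}", locus.chrom, start, rev))
            for _ in range(n_strad):
                serial += 1
                start = locus.end - read_length // 2  # spans the 3' boundary
                if start + read_length > chrom_lengths[locus.chrom]:
                    start = locus.start - read_length // 2  # fall back to 5' boundary
                out.write(_segment(f"strad{serial}", locus.chrom, start, rev))
            for _ in range(n_anti):
                serial += 1
                start = int(rng.integers(locus.start, hi + 1))
                out.write(_segment(f"anti{serial}", locus.chrom, start, not rev))
        for k in range(n_unmapped):
            seg = pysam.AlignedSegment()
            seg.query_name = f"unmapped{k + 1}"
            seg.query_sequence = "A" * read_length
            seg.flag = 4
            seg.reference_id = -1
            seg.reference_start = -1
            out.write(seg)
    return expected


def simulate_sam_corpus(
    manifest: GroundTruthManifest,
    outdir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Path], pd.DataFrame, dict[str, int], dict[str, str]]:
    """Per-sample SAM files realising the simulated counts.

    Straddling and antisense reads are added per locus at the configured
    fractions; they are mapped records (so they enter the per-sample total)
    but must not be counted on any locus.  Returns the SAM paths, the
    expected count matrix, per-sample totals (mapped records emitted) and the
    group labels.
    """
    config = manifest.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    counts, _, groups = simulate_counts(manifest, rng)
    loci = manifest.re_loci()
    paths: dict[str, Path] = {}
    totals: dict[str, int] = {}
    for s in counts.columns:
        plan = {}
        for locus in loci:
            c = int(counts.loc[locus.locus_id, s])
            plan[locus.locus_id] = (
                c,
                round(config.straddler_fraction * c),
                round(config.antisense_fraction * c),
            )
        path = outdir / f"{s}.sam"
        write_labeled_sam(
            path, loci, manifest.chrom_lengths, plan,
            read_length=config.read_length, rng=rng,
        )
        paths[s] = path
        totals[s] = int(sum(sum(v) for v in plan.values()))
    pd.DataFrame({"sample_id": list(totals), "total_mapped_reads": list(totals.values())}).to_csv(
        outdir / "totals.tsv", sep="\t", index=False
    )
    return paths, counts, totals, groups


# ---------------------------------------------------------------------------
# target-list fixtures
# ---------------------------------------------------------------------------

def simulate_target_fixtures(
    outdir: str | Path,
    rng: np.random.Generator | None = None,
    n_common_across_types: int = 99,
    n_down_in_common: int = 5,
    n_up_in_common: int = 10,
    n_type_unique: int = 25,
    n_pairwise: int = 8,
    n_db_common: int = 317,
    n_db_unique: int = 40,
) -> dict:
    """Gene-list fixtures with known set arithmetic.

    Emits three per-site-type target lists whose three-way intersection has
    exactly ``n_common_across_types`` genes (``n_down_in_common`` of them
    down-regulated in the DEG table), plus two database-style lists with an
    intersection of exactly ``n_db_common`` genes.  The returned manifest
    records every expected set so the integration stage can be checked
    without re-deriving anything.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(0)
    if n_down_in_common + n_up_in_common > n_common_across_types:
        raise ValueError("DEG calls exceed the common-set size")

    serial = [0]

    def fresh(n: int) -> list[str]:
        out = [f"SYNGENE{serial[0] + i + 1:05d}" for i in range(n)]
        serial[0] += n
        return out

    common = fresh(n_common_across_types)
    uniq = {t: fresh(n_type_unique) for t in ("8M", "7A1", "7M8")}
    pair = {p: fresh(n_pairwise) for p in (("8M", "7A1"), ("8M", "7M8"), ("7A1", "7M8"))}
    type_sets = {
        t: common + uniq[t] + [g for p, gs in pair.items() if t in p for g in gs]
        for t in ("8M", "7A1", "7M8")
    }
    down = common[:n_down_in_common]
    up = common[n_down_in_common : n_down_in_common + n_up_in_common]
    deg_rows = (
        [{"gene": g, "log2fc": -2.5, "p_value": 0.001} for g in down]
        + [{"gene": g, "log2fc": 2.0, "p_value": 0.004} for g in up]
        + [{"gene": g, "log2fc": 0.1, "p_value": 0.8} for g in fresh(30)]
    )
    db_common = fresh(n_db_common)
    db_a = db_common + fresh(n_db_unique)
    db_b = db_common + fresh(n_db_unique)

    for t, genes in type_sets.items():
        shuffled = list(genes)
        rng.shuffle(shuffled)
        (outdir / f"targets_{t}.txt").write_text("\n".join(shuffled) + "\n")
    # mixed case on purpose: symbol normalization is part of the contract
    (outdir / "db_mirdb.txt").write_text("\n".join(g.lower() for g in db_a) + "\n")
    (outdir / "db_targetscan.txt").write_text("\n".join(db_b) + "\n")
    pd.DataFrame(deg_rows).to_csv(outdir / "degs.tsv", sep="\t", index=False)

    manifest = {
        "expected_common_across_types": sorted(common),
        "expected_down_in_common": sorted(down),
        "expected_final": sorted(set(common) - set(down)),
        "expected_db_common": sorted(db_common),
        "n_common_across_types": n_common_across_types,
        "n_final": n_common_across_types - n_down_in_common,
        "n_db_common": n_db_common,
    }
    with open(outdir / "targets_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
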