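# Methods

## Scope and model

`retroce` screens two-group bulk RNA-seq for retroelement (RE) transcripts
that behave as competing endogenous RNAs. The causal model is deliberately
minimal: an RE transcript carrying seed-match sites for a miRNA dilutes
that miRNA's effective concentration in proportion to its own abundance
and its site copy number; if the RE rises in tumours, the miRNA's target
genes should escape repression. The pipeline does not model titration
stoichiometry or binding kinetics — it ranks candidates by combining
(i) differential RE expression, (ii) seed-site content, and (iii) the
behaviour of externally predicted target genes.

## Coordinates and the intergenic filter

All intervals are 0-based half-open internally. RepeatMasker `.out` rows
(1-based inclusive, strand `C` = minus) and GTF/GFF features (1-based
inclusive) are converted on ingest; rmsk-style tables and BED pass through
unchanged. A gene "body" is the full gene span; genes present only as
transcripts are aggregated to the min-start/max-end span per `gene_id`
(gffutils parses the file; the span union is computed here because gene
inference from transcript-only GTFs is not something the parser provides).

The intergenic filter removes an RE locus whole whenever it overlaps any
gene body by ≥ 1 bp on the same strand (the behaviour of
`bedtools intersect -s -v`). A stricter `any_strand` mode that also
removes antisense overlaps is provided because the two readings of the
upstream protocol differ; the same-strand mode is the default and the two
outputs are nested (any-strand survivors ⊆ same-strand survivors), so the
choice is auditable. The interval arithmetic itself is delegated to
pyranges.

## Read counting and normalisation

An alignment is attributed to a locus iff its reference span is fully
contained in the locus interval **and** its strand matches the locus
strand (`bedtools multicov -s -f 1` semantics). No MAPQ or duplicate
filtering is applied; multi-mapped reads count at every reported
alignment; one read may count toward several containing loci. The
per-sample total is the number of mapped records in the file. Expression
is RPKM: `count × 10⁹ / (length_bp × total_mapped_reads)` — invariant
under joint scaling of counts and depth.

Loci then pass a size/expression filter: length ≥ `min_length_bp`
(default 200 bp, below which a locus cannot hold many sites and its RPKM
is unstable) and RPKM ≥ `min_rpkm` (default 1) in at least `min_samples`
samples (default 1). The thresholds are explicit configuration and are
echoed in every output header.

## Differential screening

The two-group screen is Welch's two-sided t-test on `log2(RPKM + ε)` with
`ε = 0.25` by default; the fold change is
`log2((mean_tumor + ε) / (mean_normal + ε))` on the raw RPKM scale. A
feature is significant when `p < α` (default 0.05) **and**
`|log2FC| > fc_threshold` (default 1, i.e. 2-fold). Welch was chosen over
the pooled-variance t-test because tumour groups are routinely more
variable than normals; the pseudocount keeps zero-RPKM loci finite and
shrinks fold changes of barely expressed loci toward zero. No
multiple-testing correction is applied by default (the volcano-style
`p < α` call is the screen's contract); Benjamini–Hochberg is available
behind a flag. Degenerate inputs are defined: zero variance in both groups
with equal means yields p = 1; a group with fewer than two samples is an
error. Tables are sorted by p ascending, ties by |log2FC| descending, then
feature id, so output order is total and reproducible.

## Seed sites and the scanner

For a mature miRNA `m` (5'→3', RNA alphabet), the target-site strings in
DNA are:

* `site_7m8 = revcomp(m[2..8])` — the 7mer-m8 site;
* `site_8m  = site_7m8 + "A"` — the 8mer site; the appended `A` is a
  literal target adenosine (position-1 adenosines are contacted by
  Argonaute, not paired to the miRNA), so it is **not** the complement of
  `m[1]`;
* `site_7a1 = revcomp(m[2..7]) + "A"` — the 7mer-A1 site, equal to
  `site_8m` without its first base.

Because the 7mer strings are a prefix and a suffix of the 8mer string,
every 8mer occurrence textually contains one occurrence of each 7mer. The
scanner therefore applies a precedence rule — an 8mer match at offset *o*
suppresses the 7mer-m8 match at *o* and the 7mer-A1 match at *o + 1* — so
the three classes partition physical sites and their proportions are
well-defined. miRNAs sharing positions 2–8 are collapsed into one seed
family (the maximal seed any site type uses); family display labels trim
arm and paralogue suffixes (`hsa-let-7a-5p` → `hsa-let-7`).

Scanning operates on the sense (transcript) sequence of each locus only:
sequences are extracted strand-aware (minus-strand loci are
reverse-complemented, as `bedtools getfasta -s` would), uppercased
(genomic repeats are typically soft-masked), and ambiguity codes never
match. Only the seed is evaluated — no context scoring, 3'-supplementary
pairing, 6mer sites or accessibility, which is the main simplification
relative to full target-prediction pipelines.

## MRE expression and ranking

The MRE expression of a (family, site type) in a sample is the
site-count-weighted sum of the RPKM of the loci carrying that site:
`value = Σ_loci n_sites × RPKM`. The weighting reflects that a transcript
with more copies of a site contributes proportionally more sponge
capacity; a `presence` mode (each carrying locus counts once) is retained
for sensitivity analysis, and the mode used is recorded in the output
provenance. The differential MRE screen applies the identical statistical
contract as the RE screen. Top-k ranking among significant rows orders by
|log2FC|, ties by p then identifier.

Site-type proportions are percentages of site records per type over all
detected sites, each rounded to the configured precision (default 0.1),
so the three values sum to 100 within ±0.5.

## Target integration

Predicted target lists are consumed as flat symbol files (the upstream
databases are web services; the package does no network access). Symbols
are uppercased and stripped before any set operation. The released-gene
call is: intersect the per-site-type target sets three ways, then remove
genes whose DEG direction is `down` (`p < α` and `log2FC < −threshold`);
genes absent from the DEG table are kept, since only demonstrable
down-regulation contradicts the release hypothesis. No alias or ortholog
mapping is attempted — cross-species use assumes the caller provides
comparable symbol spaces.

## Synthetic data: what it emulates, and what it does not

The generator emulates a paired-design two-group RE expression study at
desk scale. Defaults: 2 chromosomes × 60 kb, 40 RE loci of 300–800 bp
(LINE: L1/L2/CR1, LTR: ERV1/ERVL/ERVL-MaLR), 20% of loci overlapping a
gene on the same strand and 10% on the opposite strand, 5 synthetic
miRNAs, 5 normal vs 5 tumour samples, log-normal baseline expression
(mean 5, SD 1 on the log2-RPKM scale), per-sample log-normal noise of
SD 0.3, a planted log2 fold change of 2 on 10% of loci (all increases, on
intergenic loci), and a nominal depth of 2 × 10⁶ mapped reads realised as
Poisson counts. One miRNA family's sites are planted exclusively on the
fold-change loci (the recoverable ceRNA signal); other families are
planted on null loci as decoys; by default two sites of each of the three
types per planted locus.

Site planting is verified by an internal window-enumeration matcher that
is independent of the scanner: after stamping, any accidental match of any
tracked family is scrubbed by randomising a base outside every planted
window, and draws that cannot be scrubbed are rejected wholesale.
Synthetic miRNA seeds are additionally regenerated until no family's
7-mer site string is a substring of another family's 8mer site, so planted
sites of one family can never create detections of another. SAM records
are minimal single-end ungapped alignments; straddling reads (crossing a
locus boundary) and antisense reads are emitted as deliberate,
deterministic negative labels that a correct counter must ignore, while
still entering the per-sample mapped total.

The manifest predicts, without running the pipeline, the exact outcome of
intergenic filtering, read counting, site scanning, type proportions and
target filtering — which is what makes recovery tests exact rather than
statistical wherever the operation is deterministic.

The generator does **not** emulate: sequence divergence between repeat
copies (so no multi-mapping ambiguity — the very feature that makes real
RE quantification hard), splicing or gapped alignments, fragment-level
paired-end structure, library-size imbalance, down-regulated REs (planted
effects are increases), GC or length bias, or real seed-family structure.
Passing recovery tests therefore demonstrates correctness of the
implemented contracts, not robustness to alignment ambiguity, and
reported sensitivity under the default noise model (≈ 1.0 at a 4-fold
effect, n = 5 vs 5, σ = 0.3) should be read as an upper bound for real
data.

## Problem sizes used in the recovery studies

Scanner/oracle agreement is measured on 1,000 random 1 kb sequences × 50
random miRNAs; planted-site recovery on an n ∈ {0, 1, 3, 10} grid over all
three site types and two families; differential recovery on 100 simulated
studies of 200 loci (10% non-null) each; end-to-end ceRNA recovery on 100
full corpus runs with the default 40-locus design. These sizes give the
Monte-Carlo estimates two-digit stability while keeping a full validation
run in the tens of seconds.

## Numerical and design notes

* The pipeline config hash stamped into output headers covers the
  analytical parameters only, not the output directory, so reruns into
  different directories are byte-identical.
* `differential_expression` maps a NaN Welch p (zero variance, equal
  means) to 1.0; infinite t statistics (zero variance, unequal means)
  give p = 0, which is the correct limit.
* Scanner output is sorted by (offset, family, type) and is invariant to
  the order of the supplied pattern list; duplicate families in the list
  are scanned once.
* BED round-trips preserve the locus core (coordinates, strand, id); the
  repeat name/class/family are annotation-side attributes and are carried
  by the rmsk/`.out` dialects, not by BED6.

## Known limitations

* Counting takes alignments at face value: no EM reassignment of
  multi-mapped reads (TEtranscripts/Telescope-style), no RSEM-style
  abundance estimation.
* Only the three canonical seed-site classes are scanned; weaker 6mer and
  offset sites, and all context scoring, are out of scope.
* The MRE aggregation weighting (site-count vs presence) changes absolute
  MRE expression values; rankings on the synthetic corpus are insensitive
  to it, but real analyses should state the mode (it is recorded in the
  output provenance).
* Cross-species target integration is symbol-based; orthology mapping is
  the caller's responsibility.
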