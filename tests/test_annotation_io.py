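import pytest

from retroce.annotation_io import (
    GeneInterval,
    RELocus,
    filter_re_classes,
    parse_gene_bodies,
    parse_repeatmasker,
    read_bed,
    subtract_gene_overlaps,
    write_bed,
)

from oracles import overlapping_pairs

RM_OUT_HEADER = (
    "   SW  perc perc perc  query  position in query  matching repeat\n"
    "score  div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
    "\n"
)

# 3 LINE, 2 LTR, 1 Simple_repeat
RM_OUT_ROWS = """\
 1500 10.0 0.5 0.5 chr1 1001 1100 (8900) C L1M5 LINE/L1 1 100 (0) 1
 1400 11.0 0.5 0.5 chr1 2001 2500 (7500) + L2a LINE/L2 1 500 (0) 2
 1300 12.0 0.5 0.5 chr1 3001 3300 (6700) + CR1-L LINE/CR1 1 300 (0) 3
 1200 13.0 0.5 0.5 chr2 1001 1600 (8400) + MLT1A LTR/ERVL-MaLR 1 600 (0) 4
 1100 14.0 0.5 0.5 chr2 2001 2400 (7600) C HERVK LTR/ERV1 1 400 (0) 5
 1000 15.0 0.5 0.5 chr2 3001 3050 (6950) + (AT)n Simple_repeat 1 50 (0) 6
"""


@pytest.fixture()
def rm_out_file(tmp_path):
    path = tmp_path / "fixture.out"
    path.write_text(RM_OUT_HEADER + RM_OUT_ROWS)
    return path


class TestParseRepeatmasker:
    def test_out_coordinates_become_zero_based_half_open(self, rm_out_file):
        loci = parse_repeatmasker(rm_out_file, "rm_out")
        first = loci[0]
        assert (first.chrom, first.start, first.end) == ("chr1", 1000, 1100)
        assert first.strand == "-"  # 'C' means minus
        assert (first.rep_class, first.rep_family, first.rep_name) == ("LINE", "L1", "L1M5")

    def test_fixture_row_count_and_classes(self, rm_out_file):
        loci = parse_repeatmasker(rm_out_file, "rm_out")
        assert len(loci) == 6
        assert [l.rep_class for l in loci].count("LINE") == 3
        assert [l.rep_class for l in loci].count("LTR") == 2

    def test_class_only_field_reuses_class_as_family(self, rm_out_file):
        simple = parse_repeatmasker(rm_out_file, "rm_out")[-1]
        assert simple.rep_class == simple.rep_family == "Simple_repeat"

    def test_rmsk_table_passes_half_open_coordinates_through(self, tmp_path):
        path = tmp_path / "rmsk.tsv"
        path.write_text(
            "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n"
            "chr1\t500\t700\t+\tL1M5\tLINE\tL1\n"
        )
        (locus,) = parse_repeatmasker(path, "rmsk")
        assert (locus.start, locus.end, locus.strand) == (500, 700, "+")

    def test_malformed_row_error_names_line_number(self, tmp_path):
        path = tmp_path / "bad.out"
        path.write_text(RM_OUT_HEADER + " 1500 10.0 bad row\n")
        with pytest.raises(ValueError, match="line 4"):
            parse_repeatmasker(path, "rm_out")

    def test_unknown_dialect_rejected(self, rm_out_file):
        with pytest.raises(ValueError, match="dialect"):
            parse_repeatmasker(rm_out_file, "bedpe")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_repeatmasker(tmp_path / "nope.out", "rm_out")


class TestFilterClasses:
    def test_line_ltr_subset_of_fixture(self, rm_out_file):
        loci = parse_repeatmasker(rm_out_file, "rm_out")
        kept = filter_re_classes(loci, {"LINE", "LTR"})
        assert len(kept) == 5
        assert kept == [l for l in loci if l.rep_class in {"LINE", "LTR"}]  # order preserved

    def test_no_matching_class_gives_empty_list(self, rm_out_file):
        loci = [l for l in parse_repeatmasker(rm_out_file, "rm_out") if l.rep_class == "Simple_repeat"]
        assert filter_re_classes(loci, {"LINE", "LTR"}) == []

    def test_keeping_all_classes_is_identity(self, rm_out_file):
        loci = parse_repeatmasker(rm_out_file, "rm_out")
        assert filter_re_classes(loci, {l.rep_class for l in loci}) == loci

    def test_empty_keep_set_rejected(self):
        with pytest.raises(ValueError):
            filter_re_classes([], set())


class TestParseGeneBodies:
    def test_gtf_gene_line_converted_to_half_open(self, tmp_path):
        path = tmp_path / "g.gtf"
        path.write_text('chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "G1";\n')
        (gene,) = parse_gene_bodies(path)
        assert (gene.start, gene.end, gene.strand) == (100, 200, "+")

    def test_transcript_only_gene_gets_span_union(self, tmp_path):
        path = tmp_path / "g.gtf"
        path.write_text(
            'chr1\tsrc\ttranscript\t101\t300\t.\t+\t.\tgene_id "G1"; transcript_id "t1";\n'
            'chr1\tsrc\ttranscript\t251\t500\t.\t+\t.\tgene_id "G1"; transcript_id "t2";\n'
        )
        (gene,) = parse_gene_bodies(path)
        assert (gene.start, gene.end) == (100, 500)

    def test_fixture_gene_count(self, tmp_path):
        lines = [
            f'chr1\tsrc\tgene\t{i * 1000 + 1}\t{i * 1000 + 500}\t.\t+\t.\tgene_id "G{i}";\n'
            for i in range(4)
        ]
        path = tmp_path / "four.gtf"
        path.write_text("".join(lines))
        assert len(parse_gene_bodies(path)) == 4

    def test_no_gene_features_rejected(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text('chr1\tsrc\tCDS\t1\t10\t.\t+\t0\tother_id "x";\n')
        with pytest.raises(ValueError, match="no gene features"):
            parse_gene_bodies(path)


class TestSubtractGeneOverlaps:
    RE = RELocus("chr1", 100, 200, "+", "L1M5", "LINE", "L1")

    def test_same_strand_overlap_removes_locus(self):
        gene = GeneInterval("G", "chr1", 150, 250, "+")
        assert subtract_gene_overlaps([self.RE], [gene], "same_strand") == []

    def test_opposite_strand_overlap_retained_in_same_strand_mode(self):
        gene = GeneInterval("G", "chr1", 150, 250, "-")
        assert subtract_gene_overlaps([self.RE], [gene], "same_strand") == [self.RE]

    def test_opposite_strand_overlap_removed_in_any_strand_mode(self):
        gene = GeneInterval("G", "chr1", 150, 250, "-")
        assert subtract_gene_overlaps([self.RE], [gene], "any_strand") == []

    def test_abutting_half_open_intervals_do_not_overlap(self):
        gene = GeneInterval("G", "chr1", 200, 300, "+")
        assert subtract_gene_overlaps([self.RE], [gene], "same_strand") == [self.RE]

    def test_unknown_strand_mode_rejected(self):
        with pytest.raises(ValueError, match="strand_mode"):
            subtract_gene_overlaps([self.RE], [], "antisense")

    def test_any_strand_survivors_subset_of_same_strand(self, corpus):
        _, manifest = corpus
        loci = manifest.re_loci()
        genes = [
            GeneInterval(g["gene_id"], g["chrom"], g["start"], g["end"], g["strand"])
            for g in manifest.data["genes"]
        ]
        same = {l.locus_id for l in subtract_gene_overlaps(loci, genes, "same_strand")}
        any_ = {l.locus_id for l in subtract_gene_overlaps(loci, genes, "any_strand")}
        assert any_ <= same

    def test_no_residual_same_strand_overlap_by_brute_force(self, corpus):
        _, manifest = corpus
        loci = manifest.re_loci()
        genes = [
            GeneInterval(g["gene_id"], g["chrom"], g["start"], g["end"], g["strand"])
            for g in manifest.data["genes"]
        ]
        kept = subtract_gene_overlaps(loci, genes, "same_strand")
        assert overlapping_pairs(kept, genes, same_strand_only=True) == []


def test_bed_round_trip_preserves_core_fields(tmp_path, corpus):
    _, manifest = corpus
    loci = manifest.re_loci()
    path = tmp_path / "loci.bed"
    write_bed(loci, path)
    back = read_bed(path)
    assert [(l.chrom, l.start, l.end, l.strand, l.locus_id) for l in back] == [
        (l.chrom, l.start, l.end, l.strand, l.locus_id) for l in loci
    ]
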