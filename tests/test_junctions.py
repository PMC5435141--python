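"""Junction-table I/O, coordinate conventions, and sequence extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronseek.junctions import (
    GenomeRef,
    IntronContext,
    JunctionParseError,
    SpliceJunction,
    extract_intron_context,
    intron_length,
    junction_to_bed,
    read_junction_table,
    reverse_complement,
    write_bed,
    write_junction_table,
)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestReadJunctionTable:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "sj.tab"
        path.write_text("chr1\t101\t126\t1\t1\t0\t12\t3\t20\n")
        (j,) = read_junction_table(path, sample_id="s1")
        assert j == SpliceJunction(
            "chr1", 101, 126, "+", motif_code=1, annotated_flag=False,
            unique_reads=12, multi_reads=3, max_overhang=20, sample_id="s1",
        )

    def test_empty_file(self, tmp_path):
        path = tmp_path / "sj.tab"
        path.write_text("")
        assert read_junction_table(path) == []

    def test_zero_read_rows_are_retained(self, tmp_path):
        path = tmp_path / "sj.tab"
        path.write_text("chr1\t5\t30\t2\t0\t0\t0\t0\t0\n")
        (j,) = read_junction_table(path)
        assert j.unique_reads == 0 and j.strand == "-"

    @pytest.mark.parametrize(
        "row",
        [
            "chr1\t101\t126\t1\t1\t0\t12\t3",          # 8 columns
            "chr1\t101\t126\t1\t1\t0\tx\t3\t20",       # non-integer count
            "chr1\t200\t100\t1\t1\t0\t12\t3\t20",      # start > end
        ],
    )
    def test_malformed_row_names_line(self, tmp_path, row):
        path = tmp_path / "sj.tab"
        path.write_text("chr1\t101\t126\t1\t1\t0\t12\t3\t20\n" + row + "\n")
        with pytest.raises(JunctionParseError, match="line 2"):
            read_junction_table(path)

    def test_round_trip(self, tmp_path):
        junctions = [
            SpliceJunction("chr1", 101, 126, "+", 1, True, 12, 3, 20),
            SpliceJunction("chr2", 5, 400, "-", 2, False, 0, 1, 9),
            SpliceJunction("chr2", 7, 7, ".", 0, False, 3, 0, 5),
        ]
        path = tmp_path / "out.tab"
        write_junction_table(junctions, path)
        back = read_junction_table(path)
        assert [
            (j.chrom, j.start, j.end, j.strand, j.motif_code, j.annotated_flag,
             j.unique_reads, j.multi_reads, j.max_overhang)
            for j in back
        ] == [
            (j.chrom, j.start, j.end, j.strand, j.motif_code, j.annotated_flag,
             j.unique_reads, j.multi_reads, j.max_overhang)
            for j in junctions
        ]


class TestIntronLength:
    @pytest.mark.parametrize(
        "start,end,length", [(101, 126, 26), (50, 50, 1), (1000, 1069, 70)]
    )
    def test_inclusive_base_count(self, start, end, length):
        assert intron_length(SpliceJunction("c", start, end, "+")) == length

    def test_length_matches_extracted_sequence(self, default_dataset):
        genome = default_dataset.genome
        for ds in list(default_dataset.junctions.values())[:2]:
            for j in ds[0][:200]:
                ctx = extract_intron_context(j, genome)
                assert len(ctx.intron) == intron_length(j)


class TestExtraction:
    GENOME = GenomeRef({"c": "AAAAACCAATGTAAATTTAGGCCGGTTTTT"})
    #                    0-based:  5'CCAAT |GTAAATTTAG| GCCGG 3'
    J = SpliceJunction("c", 11, 20, "+")

    def test_plus_strand_slicing(self):
        ctx = extract_intron_context(self.J, self.GENOME, flank=5)
        assert (ctx.flank5, ctx.intron, ctx.flank3) == ("CCAAT", "GTAAATTTAG", "GCCGG")

    def test_minus_strand_is_revcomp_with_flanks_swapped(self):
        j = SpliceJunction("c", 11, 20, "-")
        plus = extract_intron_context(self.J, self.GENOME, flank=5)
        minus = extract_intron_context(j, self.GENOME, flank=5)
        assert minus.intron == reverse_complement(plus.intron)
        assert minus.flank5 == reverse_complement(plus.flank3)
        assert minus.flank3 == reverse_complement(plus.flank5)

    def test_undefined_strand_tagged_plus_orientation(self):
        j = SpliceJunction("c", 11, 20, ".")
        ctx = extract_intron_context(j, self.GENOME, flank=5)
        assert ctx.strand_undefined and ctx.intron == "GTAAATTTAG"

    def test_boundary_error(self):
        j = SpliceJunction("c", 4, 20, "+")
        with pytest.raises(IndexError):
            extract_intron_context(j, self.GENOME, flank=10)

    @settings(max_examples=50, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=40, max_size=80),
           start=st.integers(11, 20), length=st.integers(1, 15))
    def test_strand_symmetry_property(self, seq, start, length):
        genome = GenomeRef({"g": seq})
        end = start + length - 1
        if end + 10 > len(seq):
            return
        plus = extract_intron_context(SpliceJunction("g", start, end, "+"), genome)
        minus = extract_intron_context(SpliceJunction("g", start, end, "-"), genome)
        assert minus.intron == reverse_complement(plus.intron)
        assert minus.flank5 == reverse_complement(plus.flank3)


@settings(max_examples=100, derandomize=True)
@given(seq=DNA)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


class TestBed:
    def test_coordinate_convention(self, tmp_path):
        j = SpliceJunction("chr1", 101, 126, "+")
        path = tmp_path / "a.bed"
        write_bed([junction_to_bed(j, name="i1")], path)
        assert path.read_text() == "chr1\t100\t126\ti1\t0\t+\n"

    def test_empty_collection(self, tmp_path):
        path = tmp_path / "b.bed"
        write_bed([], path)
        assert path.read_text() == ""

    def test_invalid_interval(self, tmp_path):
        with pytest.raises(ValueError):
            write_bed([("c", 10, 5, ".", 0, "+")], tmp_path / "c.bed")


def test_genome_fasta_round_trip(tmp_path):
    g = GenomeRef({"chrA": "ACGTACGTNN" * 20, "chrB": "TTTTGGGG"})
    g.write_fasta(tmp_path / "g.fa")
    back = GenomeRef.from_fasta(tmp_path / "g.fa")
    for chrom in ("chrA", "chrB"):
        assert back.fetch(chrom, 0, g.chrom_length(chrom)) == g.fetch(
            chrom, 0, g.chrom_length(chrom)
        )
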