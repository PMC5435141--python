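"""End classification, chance expectation, annotation comparison, regions."""

from fractions import Fraction

import pytest

from intronseek.annotation import AnnotationModel, Transcript
from intronseek.classify import (
    assign_region,
    canonical_fraction_by_length,
    classify_ends,
    expected_canonical_fraction,
    splice_site_status,
)
from intronseek.records import IntronRecord


class TestClassifyEnds:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GTAAGTCCTTTCAG"[:9] + "TTCAG", "GT-AG"),  # GT...AG
            ("GCAAGTTTTAG"[:6] + "TTTAG", "GC-AG"),
            ("ATATCCTTAC", "AT-AC"),
            ("CATTTTTTCT", "non-canonical"),
            ("GTAAGTTTAC", "non-canonical"),  # GT..AC is not a pair
        ],
    )
    def test_terminal_dinucleotides(self, seq, expected):
        assert classify_ends(seq) == expected

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            classify_ends("GTA")


class TestExpectedCanonicalFraction:
    def test_exact_rational(self):
        assert expected_canonical_fraction() == float(Fraction(3, 256) * 100)
        assert expected_canonical_fraction() == 1.171875

    def test_scaling(self):
        assert expected_canonical_fraction(1) == pytest.approx(100 / 256)
        assert expected_canonical_fraction(256) == 100.0


class TestCanonicalFractionByLength:
    @staticmethod
    def _rec(length, canonical, strand="+"):
        seq = ("GT" + "A" * (length - 4) + "AG") if canonical else "C" * length
        r = IntronRecord("c", 1000, 1000 + length - 1, strand, intron_seq=seq)
        r.end_class = classify_ends(seq)
        return r

    def test_per_length_fractions(self):
        recs = [self._rec(20, True)] * 4 + [self._rec(20, False)] * 6
        table = canonical_fraction_by_length(recs, lengths=[19, 20])
        assert table[20] == (0.4, 0.6)
        assert table[19] is None

    def test_empty_pool(self):
        assert all(v is None for v in canonical_fraction_by_length([]).values())

    def test_undefined_strand_excluded_by_default(self):
        recs = [self._rec(20, True), self._rec(20, False, strand=".")]
        table = canonical_fraction_by_length(recs, lengths=[20])
        assert table[20] == (1.0, 0.0)
        table = canonical_fraction_by_length(
            recs, lengths=[20], include_undefined_strand=True
        )
        assert table[20] == (0.5, 0.5)

    def test_generator_knob_recovered(self, default_dataset):
        """The planted canonical probability is recovered within sampling error."""
        true = default_dataset.truth_by_class("true_short_intron")
        frac = sum(t.canonical for t in true) / len(true)
        p = default_dataset.config.canonical_probability
        # 3 sigma binomial envelope
        assert abs(frac - p) < 3 * (p * (1 - p) / len(true)) ** 0.5


@pytest.fixture
def toy_annotation():
    # one plus-strand coding gene: exons [0,100), [200,300), [400,500);
    # CDS genomic span [50, 450); annotated introns [100,200) and [300,400)
    tx = Transcript("t1", "g1", "c", "+", [(0, 100), (200, 300), (400, 500)],
                    cds=(50, 450))
    lnc = Transcript("l1", "gl", "c", "+", [(600, 800)], biotype="lncRNA")
    return AnnotationModel([tx, lnc])


class TestSpliceSiteStatus:
    def test_annotated(self, toy_annotation):
        rec = IntronRecord("c", 101, 200, "+")  # == intron [100,200)
        assert splice_site_status(rec, toy_annotation) == ("annotated", None)

    def test_as3_distance(self, toy_annotation):
        # same donor (100), acceptor 30 nt short of the annotated one (200)
        rec = IntronRecord("c", 101, 170, "+")
        assert splice_site_status(rec, toy_annotation) == ("AS-3'", 30)

    def test_as5_distance(self, toy_annotation):
        rec = IntronRecord("c", 121, 200, "+")  # novel donor at 120
        assert splice_site_status(rec, toy_annotation) == ("AS-5'", 20)

    def test_nested(self, toy_annotation):
        rec = IntronRecord("c", 221, 240, "+")  # inside exon 2, novel ends
        assert splice_site_status(rec, toy_annotation) == ("nested", None)

    def test_intergenic(self, toy_annotation):
        rec = IntronRecord("c", 901, 930, "+")
        assert splice_site_status(rec, toy_annotation) == ("intergenic", None)


class TestAssignRegion:
    def test_xbp1_style_26nt_orf_intron_frameshifts(self, toy_annotation):
        rec = IntronRecord("c", 211, 236, "+")  # 26 nt inside the CDS
        assert assign_region(rec, toy_annotation) == ("ORF", True)

    def test_30nt_orf_intron_preserves_frame(self, toy_annotation):
        rec = IntronRecord("c", 211, 240, "+")
        assert assign_region(rec, toy_annotation) == ("ORF", False)

    def test_utrs_by_strand(self, toy_annotation):
        assert assign_region(IntronRecord("c", 11, 40, "+"), toy_annotation) == (
            "5'UTR", None)
        assert assign_region(IntronRecord("c", 461, 490, "+"), toy_annotation) == (
            "3'UTR", None)

    def test_lncrna(self, toy_annotation):
        rec = IntronRecord("c", 651, 680, "+")
        assert assign_region(rec, toy_annotation) == ("lncRNA", None)

    def test_intronic(self, toy_annotation):
        rec = IntronRecord("c", 311, 340, "+")  # inside annotated intron
        assert assign_region(rec, toy_annotation) == ("intronic", None)


def test_minus_strand_classification_by_construction(default_dataset):
    """Planted labels on both strands are reproduced by classification."""
    from intronseek.classify import classify_records
    from intronseek.junctions import SpliceJunction, extract_intron_context

    truth = [t for t in default_dataset.truth_by_class("true_short_intron")]
    n_minus = 0
    recs = []
    expected = []
    for t in truth[:80]:
        rec = IntronRecord(t.chrom, t.start, t.end, t.strand)
        ctx = extract_intron_context(
            SpliceJunction(t.chrom, t.start, t.end, t.strand),
            default_dataset.genome,
        )
        rec.flank5, rec.intron_seq, rec.flank3 = ctx.flank5, ctx.intron, ctx.flank3
        recs.append(rec)
        expected.append(t)
        n_minus += t.strand == "-"
    classify_records(recs, default_dataset.annotation)
    assert n_minus > 0  # both strands exercised
    for rec, t in zip(recs, expected):
        assert rec.end_class == t.end_class
        assert rec.splice_status == t.splice_status
        assert rec.region == t.region
        assert rec.frameshift == t.frameshift
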