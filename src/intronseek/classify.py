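"""End classification, annotation comparison, region and frameshift calls.

Canonical introns are those whose terminal dinucleotides match one of the
spliceosomal consensus pairs: GT-AG or GC-AG (major spliceosome) or AT-AC
(minor spliceosome); everything else is non-canonical.  Under a uniform-base
null only 3 of the 4^4 = 256 possible terminal dinucleotide combinations are
canonical, so ~1.2% of random gaps would look canonical by chance.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

from .annotation import AnnotationModel
from .records import IntronRecord

_CANONICAL_PAIRS = (("GT", "AG", "GT-AG"), ("GC", "AG", "GC-AG"), ("AT", "AC", "AT-AC"))

_REGION_PRIORITY = ("ORF", "5'UTR", "3'UTR", "lncRNA", "intronic")


def classify_ends(intron_seq: str) -> str:
    """Classify terminal dinucleotides (DNA alphabet) of an intron sequence."""
    if len(intron_seq) < 4:
        raise ValueError("intron must be at least 4 nt to classify ends")
    seq = intron_seq.upper()
    head, tail = seq[:2], seq[-2:]
    for h, t, label in _CANONICAL_PAIRS:
        if head == h and tail == t:
            return label
    return "non-canonical"


def expected_canonical_fraction(n_allowed_pairs: int = 3) -> float:
    """Chance probability (percent) that random terminal dinucleotides look
    canonical: n_allowed_pairs / 4^4.  Default 3/256 = 1.171875%."""
    return float(Fraction(n_allowed_pairs, 256) * 100)


def canonical_fraction_by_length(
    records: Iterable[IntronRecord],
    lengths: Sequence[int] = range(10, 91),
    include_undefined_strand: bool = False,
) -> dict[int, tuple[float, float] | None]:
    """Per-length (canonical fraction, non-canonical fraction).

    Lengths with no records map to None.  Undefined-strand records are
    excluded from the curve by default (their transcribed orientation is
    unknown, so the end call is ambiguous).
    """
    counts: dict[int, list[int]] = {}
    for rec in records:
        if rec.strand == "." and not include_undefined_strand:
            continue
        c = counts.setdefault(rec.length, [0, 0])
        c[0 if rec.canonical else 1] += 1
    out: dict[int, tuple[float, float] | None] = {}
    for length in lengths:
        c = counts.get(length)
        if c is None:
            out[length] = None
        else:
            total = c[0] + c[1]
            out[length] = (c[0] / total, c[1] / total)
    return out


def _ends_for_strand(rec: IntronRecord, strand: str) -> tuple[int, int]:
    """(donor, acceptor) genomic positions for the record on ``strand``."""
    if strand == "+":
        return rec.start0, rec.end0
    return rec.end0, rec.start0


def splice_site_status(
    rec: IntronRecord, annotation: AnnotationModel, window: int = 50
) -> tuple[str, int | None]:
    """Compare a candidate's ends with the annotation.

    Returns (status, distance): ``annotated`` if both ends match an annotated
    intron exactly (any transcript); ``AS-3'`` if the 5' (donor) end matches
    an annotated donor but the acceptor is novel (distance = novel end to the
    nearest annotated acceptor); ``AS-5'`` symmetric; ``nested`` when neither
    end matches but the candidate lies within a transcript; ``intergenic``
    otherwise.  ``window`` is recorded only via the distance — matching itself
    is exact-coordinate.
    """
    strands = [rec.strand] if rec.strand in "+-" else ["+", "-"]
    for strand in strands:
        if (rec.chrom, rec.start0, rec.end0, strand) in annotation.annotated_introns:
            return "annotated", None
    for strand in strands:
        donor, acceptor = _ends_for_strand(rec, strand)
        if (rec.chrom, strand, donor) in annotation.donor_sites:
            dist = annotation.nearest_site_distance("acceptor", rec.chrom, strand, acceptor)
            return "AS-3'", dist
        if (rec.chrom, strand, acceptor) in annotation.acceptor_sites:
            dist = annotation.nearest_site_distance("donor", rec.chrom, strand, donor)
            return "AS-5'", dist
    if annotation.overlapping_transcripts(rec.chrom, rec.start0, rec.end0):
        return "nested", None
    return "intergenic", None


def _region_in_transcript(rec: IntronRecord, tx) -> str | None:
    s0, e0 = rec.start0, rec.end0
    for is0, ie0 in tx.introns():
        if is0 <= s0 and e0 <= ie0:
            return "intronic"
    if tx.biotype == "lncRNA":
        return "lncRNA"
    if tx.cds is None:
        return None
    cs, ce = tx.cds
    if s0 < ce and e0 > cs:
        return "ORF"
    upstream = e0 <= cs  # genomically left of the CDS
    if tx.strand == "+":
        return "5'UTR" if upstream else "3'UTR"
    return "3'UTR" if upstream else "5'UTR"


def assign_region(
    rec: IntronRecord, annotation: AnnotationModel
) -> tuple[str, bool | None]:
    """Assign the transcript region hosting the intron, and a frameshift call.

    Ties across host transcripts resolve by priority
    ORF > 5'UTR > 3'UTR > lncRNA > intronic (an exonic placement in any host
    outranks a purely intronic one).  Frameshift (length mod 3 != 0) applies
    only to ORF-resident introns; elsewhere it is None.
    """
    candidates = set()
    for tx in annotation.overlapping_transcripts(rec.chrom, rec.start0, rec.end0):
        region = _region_in_transcript(rec, tx)
        if region is not None:
            candidates.add(region)
    region = next((r for r in _REGION_PRIORITY if r in candidates), "intergenic")
    frameshift = (rec.length % 3 != 0) if region == "ORF" else None
    return region, frameshift


def classify_records(
    records: Iterable[IntronRecord], annotation: AnnotationModel | None = None
) -> None:
    """Fill end_class / splice_status / region / frameshift in place."""
    for rec in records:
        rec.end_class = classify_ends(rec.intron_seq)
        if annotation is not None:
            rec.splice_status, rec.as_distance = splice_site_status(rec, annotation)
            rec.region, rec.frameshift = assign_region(rec, annotation)
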