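"""Splice-junction tables, genome access, and coordinate conventions.

The junction dialect is the 9-column tab-separated table emitted by
splice-aware aligners (one row per predicted exon-exon junction)::

    chrom  start  end  strand_code  motif_code  annotated  unique  multi  overhang

``start``/``end`` are the 1-based positions of the first and last intronic
base.  Strand codes are 0 (undefined), 1 (+), 2 (-).  All other coordinate
arithmetic in this package (BED output, window construction) goes through the
0-based half-open helpers on :class:`SpliceJunction` so the inclusive/exclusive
conversion happens in exactly one place.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

_STRAND_FROM_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_FROM_STRAND = {".": 0, "+": 1, "-": 2}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement on the DNA alphabet (N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


class JunctionParseError(ValueError):
    """Raised for a malformed junction-table row; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}, line {lineno}: {message}")


@dataclass(frozen=True, slots=True)
class SpliceJunction:
    """One observed junction (candidate intron) from one replicate.

    ``start`` and ``end`` are 1-based inclusive coordinates of the first and
    last intron base, exactly as in the junction table.
    """

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' (undefined)
    motif_code: int = 0
    annotated_flag: bool = False
    unique_reads: int = 0
    multi_reads: int = 0
    max_overhang: int = 0
    sample_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    # --- coordinate helpers (0-based half-open) ---
    @property
    def start0(self) -> int:
        """0-based position of the first intron base."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (one past the last intron base)."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple:
        """Identity used for cross-replicate / cross-sample matching."""
        return (self.chrom, self.start, self.end, self.strand)


def intron_length(j: SpliceJunction) -> int:
    """Number of intronic bases: end - start + 1 (1-based inclusive coords)."""
    return j.length


def read_junction_table(path, sample_id: str = "") -> list[SpliceJunction]:
    """Parse a 9-column junction table into :class:`SpliceJunction` records.

    Rows with zero unique reads are retained; read-support filtering is a
    later pipeline stage.  Malformed rows raise :class:`JunctionParseError`
    naming the offending line.
    """
    out: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-separated tables
                fields = line.split()
            if len(fields) != 9:
                raise JunctionParseError(
                    path, lineno, f"expected 9 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = _STRAND_FROM_CODE[int(fields[3])]
                motif = int(fields[4])
                annotated = bool(int(fields[5]))
                uniq, multi, overhang = (
                    int(fields[6]),
                    int(fields[7]),
                    int(fields[8]),
                )
            except (ValueError, KeyError) as exc:
                raise JunctionParseError(path, lineno, str(exc)) from exc
            try:
                out.append(
                    SpliceJunction(
                        chrom, start, end, strand, motif, annotated,
                        uniq, multi, overhang, sample_id,
                    )
                )
            except ValueError as exc:
                raise JunctionParseError(path, lineno, str(exc)) from exc
    return out


def write_junction_table(junctions: Iterable[SpliceJunction], path) -> None:
    """Write junctions back out in the same 9-column dialect."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.chrom, j.start, j.end, _CODE_FROM_STRAND[j.strand],
                        j.motif_code, int(j.annotated_flag), j.unique_reads,
                        j.multi_reads, j.max_overhang,
                    )
                )
                + "\n"
            )


class GenomeRef:
    """In-memory genome: chromosome name -> uppercase sequence.

    Construct from a dict or from a FASTA file (via pyfaidx).  Interval
    lookups are 0-based half-open and must lie inside the chromosome.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeRef":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Plus-strand sequence of the 0-based half-open interval."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start0 < 0 or end0 > len(seq) or start0 > end0:
            raise IndexError(
                f"interval [{start0}, {end0}) outside {chrom} (len {len(seq)})"
            )
        return seq[start0:end0]

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self._seqs:
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True, slots=True)
class IntronContext:
    """Sequences around one junction, in transcribed orientation.

    ``flank5`` is always the upstream exonic flank in transcript sense; for
    minus-strand junctions all three sequences are reverse-complemented and
    the flanks swapped.  Undefined-strand junctions are reported in genomic
    plus orientation with ``strand_undefined`` set.
    """

    flank5: str
    intron: str
    flank3: str
    strand_undefined: bool = False

    @property
    def flanked(self) -> str:
        return self.flank5 + self.intron + self.flank3


def extract_intron_context(
    j: SpliceJunction, genome: GenomeRef, flank: int = 10
) -> IntronContext:
    """Extract (5' flank, intron, 3' flank) for a junction, strand-aware.

    Raises IndexError when the flanked interval falls off the chromosome;
    callers drop such junctions with a warning.
    """
    left = genome.fetch(j.chrom, j.start0 - flank, j.start0)
    intron = genome.fetch(j.chrom, j.start0, j.end0)
    right = genome.fetch(j.chrom, j.end0, j.end0 + flank)
    if j.strand == "-":
        return IntronContext(
            flank5=reverse_complement(right),
            intron=reverse_complement(intron),
            flank3=reverse_complement(left),
        )
    return IntronContext(
        flank5=left, intron=intron, flank3=right,
        strand_undefined=(j.strand == "."),
    )


def junction_to_bed(j: SpliceJunction, name: str = ".", score: int = 0) -> tuple:
    """(chrom, bed_start, bed_end, name, score, strand) for a junction."""
    return (j.chrom, j.start0, j.end0, name, score, j.strand)


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write 6-column BED (0-based half-open intervals).

    Each interval is (chrom, start, end, name, score, strand); negative
    coordinates or end < start raise ValueError.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            if start < 0 or end < start:
                raise ValueError(f"bad BED interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
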