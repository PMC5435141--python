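"""The per-candidate intron record threaded through the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from .artifacts import ArtifactFlags


@dataclass
class IntronRecord:
    """A candidate short intron with its sequence context and annotations.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the first
    and last intron base; sequences are in transcribed orientation (for
    undefined strand, genomic plus orientation, ``strand == '.'``).
    Classification fields are filled in by successive pipeline stages.
    """

    chrom: str
    start: int
    end: int
    strand: str
    intron_seq: str = ""
    flank5: str = ""
    flank3: str = ""
    end_class: str = ""  # GT-AG | GC-AG | AT-AC | non-canonical
    artifact: ArtifactFlags = field(default_factory=ArtifactFlags)
    samples_detected: int = 0
    total_unique_reads: int = 0
    splice_status: str = ""  # annotated | AS-5' | AS-3' | nested | intergenic
    as_distance: int | None = None  # unmatched end to nearest annotated site
    region: str = ""  # 5'UTR | ORF | 3'UTR | intronic | lncRNA | intergenic
    frameshift: bool | None = None
    avg_efficiency: float | None = None
    max_efficiency: float | None = None
    delta_g: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def canonical(self) -> bool:
        return self.end_class not in ("", "non-canonical")

    @property
    def flanked_seq(self) -> str:
        return self.flank5 + self.intron_seq + self.flank3

    @property
    def intron_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"
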