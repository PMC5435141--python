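"""Transcript annotation: exon/CDS structure, derived introns, splice sites.

The annotation is GTF-like (exon and CDS features with ``gene_id``,
``transcript_id`` and ``gene_biotype`` attributes).  Internally everything is
0-based half-open.  Splice-site coordinates are strand-aware: the donor (5'
splice site) of a plus-strand intron is its genomic start, of a minus-strand
intron its genomic end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by start
    cds: tuple[int, int] | None = None  # genomic CDS span
    biotype: str = "coding"  # 'coding' | 'lncRNA'

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.tx_id}")
        if any(e <= s for s, e in self.exons):
            raise ValueError(f"empty exon in {self.tx_id}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between adjacent exons (each length >= 1)."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


class AnnotationModel:
    """Queryable view over a set of transcripts."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        # (chrom, start0, end0, strand) of annotated introns
        self.annotated_introns: set[tuple] = set()
        self.donor_sites: set[tuple] = set()  # (chrom, strand, genomic pos)
        self.acceptor_sites: set[tuple] = set()
        for tx in self.transcripts:
            lo, hi = tx.span
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(lo, hi, tx)
            for s0, e0 in tx.introns():
                self.annotated_introns.add((tx.chrom, s0, e0, tx.strand))
                if tx.strand == "+":
                    self.donor_sites.add((tx.chrom, "+", s0))
                    self.acceptor_sites.add((tx.chrom, "+", e0))
                else:
                    self.donor_sites.add((tx.chrom, "-", e0))
                    self.acceptor_sites.add((tx.chrom, "-", s0))

        self._sorted_sites: dict[tuple, list[int]] = {}
        for kind, sites in (("donor", self.donor_sites), ("acceptor", self.acceptor_sites)):
            by_loc: dict[tuple, list[int]] = {}
            for chrom, strand, pos in sites:
                by_loc.setdefault((kind, chrom, strand), []).append(pos)
            for loc, positions in by_loc.items():
                self._sorted_sites[loc] = sorted(positions)

    def nearest_site_distance(
        self, kind: str, chrom: str, strand: str, pos: int
    ) -> int | None:
        """Distance (nt) from ``pos`` to the nearest annotated splice site.

        ``kind`` is 'donor' or 'acceptor'; returns None if the chrom/strand
        has no such sites.
        """
        import bisect

        positions = self._sorted_sites.get((kind, chrom, strand))
        if not positions:
            return None
        i = bisect.bisect_left(positions, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(positions[j] - pos)
                best = d if best is None else min(best, d)
        return best

    def overlapping_transcripts(self, chrom: str, start0: int, end0: int):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start0, end0)),
            key=lambda tx: tx.tx_id,
        )

    # --- GTF I/O -----------------------------------------------------------

    @classmethod
    def from_gtf(cls, path) -> "AnnotationModel":
        """Load exon/CDS features from a GTF file (gffutils, in-memory db)."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        exons: dict[str, dict] = {}
        for feat in db.all_features(order_by=("seqid", "start")):
            if feat.featuretype not in ("exon", "CDS"):
                continue
            tx_id = feat.attributes["transcript_id"][0]
            rec = exons.setdefault(
                tx_id,
                {
                    "gene_id": feat.attributes.get("gene_id", [tx_id])[0],
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": feat.attributes.get("gene_biotype", ["coding"])[0],
                    "exons": [],
                    "cds": None,
                },
            )
            iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
            if feat.featuretype == "exon":
                rec["exons"].append(iv)
            else:
                cds = rec["cds"]
                rec["cds"] = iv if cds is None else (min(cds[0], iv[0]), max(cds[1], iv[1]))
        return cls(
            Transcript(
                tx_id=tx_id,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                cds=rec["cds"],
                biotype=rec["biotype"],
            )
            for tx_id, rec in sorted(exons.items())
        )

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for tx in self.transcripts:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.tx_id}"; '
                    f'gene_biotype "{tx.biotype}";'
                )
                for s0, e0 in tx.exons:
                    fh.write(
                        f"{tx.chrom}\tintronseek\texon\t{s0 + 1}\t{e0}\t.\t"
                        f"{tx.strand}\t.\t{attrs}\n"
                    )
                if tx.cds is not None:
                    s0, e0 = tx.cds
                    # emit CDS clipped to exons so the file is well-formed
                    for xs, xe in tx.exons:
                        cs, ce = max(xs, s0), min(xe, e0)
                        if cs < ce:
                            fh.write(
                                f"{tx.chrom}\tintronseek\tCDS\t{cs + 1}\t{ce}\t.\t"
                                f"{tx.strand}\t0\t{attrs}\n"
                            )
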