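"""Cross-sample aggregation and the pooled unique-read support cutoff.

Short-intron candidates have no reference set, but the aligner also predicts
many *long* introns, some annotated and some not.  Annotated long introns are
detected in nearly every dataset; unannotated long ones in few.  The short
pool is therefore compared against the unannotated long pool: the pooled
read-support cutoff is raised until the short introns that remain are, on
average, detected in more biological samples than the unannotated long
introns.  The crossing point is recomputed on every input, never assumed;
a fixed cutoff can be supplied instead for replication-style runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import AnnotationModel
from .junctions import SpliceJunction


@dataclass
class SupportEntry:
    """Pooled evidence for one intron identity across all datasets."""

    chrom: str
    start: int
    end: int
    strand: str
    samples_detected: int
    total_unique_reads: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class SupportProfile:
    """A pool of SupportEntry plus its samples-detected distribution."""

    entries: list[SupportEntry]

    def distribution(self) -> dict[int, float]:
        counts: dict[int, int] = {}
        for e in self.entries:
            counts[e.samples_detected] = counts.get(e.samples_detected, 0) + 1
        total = sum(counts.values())
        return {k: v / total for k, v in sorted(counts.items())} if total else {}

    def mean_samples(self) -> float:
        if not self.entries:
            raise ValueError("empty pool")
        return sum(e.samples_detected for e in self.entries) / len(self.entries)


def aggregate_junctions(
    replicates_by_sample: Mapping[str, Sequence[Sequence[SpliceJunction]]],
    cutoffs: Mapping[str, int],
) -> dict[tuple, SupportEntry]:
    """Pool junctions by identity across datasets.

    A junction counts as detected in a dataset when it reaches that dataset's
    npIDR-derived unique-read cutoff in at least one replicate; its pooled
    ``total_unique_reads`` sums every observation (all replicates, including
    sub-cutoff ones) so pooled support reflects total evidence.
    """
    pooled: dict[tuple, SupportEntry] = {}
    detected_in: dict[tuple, set] = {}
    for sample_id, replicates in replicates_by_sample.items():
        cutoff = cutoffs[sample_id]
        for rep in replicates:
            for j in rep:
                entry = pooled.get(j.key)
                if entry is None:
                    entry = SupportEntry(
                        j.chrom, j.start, j.end, j.strand,
                        samples_detected=0, total_unique_reads=0,
                    )
                    pooled[j.key] = entry
                entry.total_unique_reads += j.unique_reads
                if j.unique_reads >= cutoff:
                    detected_in.setdefault(j.key, set()).add(sample_id)
    out: dict[tuple, SupportEntry] = {}
    for key, entry in pooled.items():
        n = len(detected_in.get(key, ()))
        if n >= 1:
            entry.samples_detected = n
            out[key] = entry
    return out


def build_support_profiles(
    aggregated: Mapping[tuple, SupportEntry],
    annotation: AnnotationModel,
    short_keys: Iterable[tuple] | None = None,
    min_len: int = 10,
    max_len: int = 70,
) -> dict[str, SupportProfile]:
    """Split pooled introns into short / long-annotated / long-unannotated.

    ``short_keys``, when given, restricts the short pool to identities that
    survived the artifact screens.  Long introns (> ``max_len``) are split by
    exact end match against the annotation (either strand for undefined).
    """
    short_keys = set(short_keys) if short_keys is not None else None
    pools: dict[str, list[SupportEntry]] = {
        "short": [], "long_annotated": [], "long_unannotated": []
    }
    for key, entry in aggregated.items():
        if min_len <= entry.length <= max_len:
            if short_keys is None or key in short_keys:
                pools["short"].append(entry)
        elif entry.length > max_len:
            strands = [entry.strand] if entry.strand in "+-" else ["+", "-"]
            is_annot = any(
                (entry.chrom, entry.start - 1, entry.end, s)
                in annotation.annotated_introns
                for s in strands
            )
            pools["long_annotated" if is_annot else "long_unannotated"].append(entry)
    return {name: SupportProfile(entries) for name, entries in pools.items()}


class NoQualifyingCutoff(ValueError):
    def __init__(self, table):
        self.table = table
        super().__init__("short pool never favors more samples than the "
                         "unannotated long pool at any tested cutoff")


def select_read_cutoff(
    short_profile: SupportProfile,
    unannotated_long_profile: SupportProfile,
    n_max: int = 50,
) -> tuple[int, list[tuple[int, int, float]]]:
    """Smallest pooled-read cutoff at which the restricted short pool is
    detected in strictly more samples (on average) than unannotated long
    introns.

    Returns (cutoff, table) where table rows are
    (cutoff, n_short_kept, mean_samples_detected); raises
    :class:`NoQualifyingCutoff` with the full table if none qualifies.
    """
    reference = unannotated_long_profile.mean_samples()
    table: list[tuple[int, int, float]] = []
    chosen = None
    for n in range(1, n_max + 1):
        kept = [e for e in short_profile.entries if e.total_unique_reads >= n]
        if not kept:
            break
        mean = sum(e.samples_detected for e in kept) / len(kept)
        table.append((n, len(kept), mean))
        if chosen is None and mean > reference:
            chosen = n
    if chosen is None:
        raise NoQualifyingCutoff(table)
    return chosen, table
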