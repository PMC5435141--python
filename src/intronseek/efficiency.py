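"""Splicing efficiency from interval read counts.

For every candidate intron three 10-nt genomic windows are counted: one in
the 5' flanking exon (-15..-5 from the intron start), one centred on the
intron middle, and one in the 3' flanking exon (+5..+15 from the intron end).
Efficiency is::

    eff = 100 - 100 * mid / ((flank5 + flank3) / 2)

clamped below at 0 (an unspliced, fully covered intron scores 0; a fully
spliced one scores 100).  A zero flank average leaves the value undefined and
the observation is excluded from per-intron averages.

Windows are genomic (strand-independent): the statistic is symmetric in the
two flanks.  Reads can come from a precomputed window-count table or be
counted from alignments (a read overlaps a window if any aligned block shares
at least one base with it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EfficiencyWindows:
    """The three 10-nt count windows for one intron (0-based half-open)."""

    chrom: str
    flank5: tuple[int, int]
    mid: tuple[int, int]
    flank3: tuple[int, int]


def efficiency_windows(chrom: str, start: int, end: int,
                       chrom_length: int | None = None) -> EfficiencyWindows:
    """Build the three windows for a 1-based inclusive intron [start, end].

    With s0 = start-1 and e0 = end: flank5 window [s0-15, s0-5), mid window
    [m-5, m+5) with m = floor((s0+e0)/2), flank3 window [e0+5, e0+15).
    Raises ValueError when a window falls outside the chromosome (the caller
    marks the record undefined).
    """
    if end - start + 1 < 10:
        raise ValueError("intron shorter than 10 nt")
    s0, e0 = start - 1, end
    m = (s0 + e0) // 2
    windows = EfficiencyWindows(
        chrom=chrom,
        flank5=(s0 - 15, s0 - 5),
        mid=(m - 5, m + 5),
        flank3=(e0 + 5, e0 + 15),
    )
    lo = windows.flank5[0]
    hi = windows.flank3[1]
    if lo < 0 or (chrom_length is not None and hi > chrom_length):
        raise ValueError(f"windows [{lo}, {hi}) outside {chrom}")
    return windows


def splicing_efficiency(reads_5flank: float, reads_mid: float,
                        reads_3flank: float) -> float | None:
    """The clamped efficiency statistic; None when the flank average is 0."""
    if min(reads_5flank, reads_mid, reads_3flank) < 0:
        raise ValueError("read counts must be non-negative")
    flank = (reads_5flank + reads_3flank) / 2.0
    if flank == 0:
        return None
    return max(0.0, 100.0 - 100.0 * reads_mid / flank)


class TableCoverage:
    """Window counts from a precomputed TSV.

    Columns: intron_id, sample_id, reads_5flank, reads_mid, reads_3flank.
    """

    COLUMNS = ["intron_id", "sample_id", "reads_5flank", "reads_mid", "reads_3flank"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"coverage table missing columns {sorted(missing)}")
        if (frame[self.COLUMNS[2:]] < 0).any().any():
            raise ValueError("negative counts in coverage table")
        self._frame = frame
        self._lookup = {
            (row.intron_id, row.sample_id): (
                row.reads_5flank, row.reads_mid, row.reads_3flank
            )
            for row in frame.itertuples(index=False)
        }
        self.sample_ids = sorted(frame["sample_id"].unique())

    @classmethod
    def from_tsv(cls, path) -> "TableCoverage":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def window_counts(self, intron_id: str, sample_id: str):
        return self._lookup.get((intron_id, sample_id))


def alignment_window_counts(
    path, windows_by_id: Mapping[str, EfficiencyWindows]
) -> dict[str, tuple[int, int, int]]:
    """Count reads overlapping each intron's three windows in a SAM/BAM file.

    A read is counted for a window when at least one of its aligned blocks
    overlaps the window by >= 1 base (junction-spanning reads therefore count
    toward the flank windows they touch but not toward the excised middle).
    Streams the whole file once, so an unindexed plain-text SAM works.
    """
    import pysam

    counts = {iid: [0, 0, 0] for iid in windows_by_id}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            blocks = read.get_blocks()
            chrom = read.reference_name
            for iid, w in windows_by_id.items():
                if w.chrom != chrom:
                    continue
                for wi, (ws, we) in enumerate((w.flank5, w.mid, w.flank3)):
                    if any(bs < we and be > ws for bs, be in blocks):
                        counts[iid][wi] += 1
    return {iid: tuple(c) for iid, c in counts.items()}


def coverage_from_alignments(
    sam_paths: Mapping[str, object],
    windows_by_id: Mapping[str, EfficiencyWindows],
) -> TableCoverage:
    """Build a :class:`TableCoverage` by counting one SAM/BAM per sample."""
    rows = []
    for sample_id in sorted(sam_paths):
        counts = alignment_window_counts(sam_paths[sample_id], windows_by_id)
        for iid in sorted(counts):
            r5, rm, r3 = counts[iid]
            rows.append((iid, sample_id, r5, rm, r3))
    return TableCoverage(pd.DataFrame(rows, columns=TableCoverage.COLUMNS))


def compute_efficiencies(records, coverage: TableCoverage,
                         sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-intron, per-sample efficiencies; fills avg/max on each record.

    Returns the long-form table (one row per intron x sample with counts and
    the efficiency, NaN when undefined).
    """
    sample_ids = list(sample_ids) if sample_ids is not None else coverage.sample_ids
    rows = []
    for rec in records:
        values = []
        for sample_id in sample_ids:
            counts = coverage.window_counts(rec.intron_id, sample_id)
            if counts is None:
                continue
            r5, rm, r3 = counts
            eff = splicing_efficiency(r5, rm, r3)
            rows.append((rec.intron_id, sample_id, r5, rm, r3,
                         math.nan if eff is None else eff))
            if eff is not None:
                values.append(eff)
        rec.avg_efficiency = sum(values) / len(values) if values else None
        rec.max_efficiency = max(values) if values else None
    return pd.DataFrame(
        rows, columns=["intron_id", "sample_id", "reads_5flank", "reads_mid",
                       "reads_3flank", "efficiency"],
    )


def bin_and_correlate(
    keys: Sequence[float],
    efficiencies: Sequence[float],
    bin_size: int = 20,
    descending: bool = True,
) -> tuple[pd.DataFrame, float, float]:
    """Rank by key, bin in consecutive groups, correlate bin means.

    Records are sorted by ``keys`` (descending by default: progressively less
    read support, or progressively lower folding free energy, in each
    subsequent bin); consecutive groups of ``bin_size`` are formed (the last
    group may be smaller) and the Pearson correlation is computed across the
    per-bin means of key and efficiency.  Returns (bin table, R, p).
    """
    if len(keys) != len(efficiencies):
        raise ValueError("keys and efficiencies differ in length")
    order = np.argsort(np.asarray(keys, dtype=float), kind="stable")
    if descending:
        order = order[::-1]
    k = np.asarray(keys, dtype=float)[order]
    e = np.asarray(efficiencies, dtype=float)[order]
    n_bins = math.ceil(len(k) / bin_size)
    if n_bins < 2:
        raise ValueError("fewer than 2 bins; correlation undefined")
    rows = []
    for b in range(n_bins):
        sl = slice(b * bin_size, (b + 1) * bin_size)
        rows.append((b, sl.stop - sl.start if sl.stop <= len(k) else len(k) - sl.start,
                     float(np.mean(k[sl])), float(np.mean(e[sl]))))
    table = pd.DataFrame(rows, columns=["bin", "n", "mean_key", "mean_efficiency"])
    if table["mean_efficiency"].nunique() < 2 or table["mean_key"].nunique() < 2:
        return table, math.nan, math.nan
    r, p = stats.pearsonr(table["mean_key"], table["mean_efficiency"])
    return table, float(r), float(p)
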