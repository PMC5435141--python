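"""Non-parametric irreproducible discovery rate (npIDR) between replicates.

There is no reference set against which short-intron calls could be given a
conventional FDR, so reproducibility between the two biological replicates of
a sample stands in for it: junctions are restricted to those with at least
``n`` unique reads in one replicate and scored by the fraction that is present
(>= 1 unique read) in the other replicate.  The per-sample minimum read
support is the smallest ``n`` whose reproducibility exceeds a threshold
(default 0.90).

The statistic is symmetrised: the directional rates r(A->B) and r(B->A) are
averaged; a direction whose eligible set is empty contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .junctions import SpliceJunction


class NoJunctionsAtCutoff(ValueError):
    """Both replicates have empty eligible sets at the requested cutoff."""


class CutoffUnreachable(ValueError):
    """No cutoff up to n_max reached the reproducibility threshold."""

    def __init__(self, sample_id: str, best_n: int, best_value: float):
        self.sample_id = sample_id
        self.best_n = best_n
        self.best_value = best_value
        super().__init__(
            f"sample {sample_id!r}: npIDR threshold not reached; "
            f"best was {best_value:.4f} at cutoff {best_n}"
        )


@dataclass
class NpidrCurve:
    """Reproducibility as a function of the minimum-unique-read cutoff."""

    sample_id: str
    values: dict[int, float]  # cutoff n -> reproducibility in [0, 1]
    chosen_cutoff: int
    threshold: float = 0.90


def _directional(eligible: Iterable[tuple], other_keys: set) -> tuple[int, int]:
    hits = total = 0
    for key in eligible:
        total += 1
        if key in other_keys:
            hits += 1
    return hits, total


def npidr_at_cutoff(
    rep_a: Sequence[SpliceJunction],
    rep_b: Sequence[SpliceJunction],
    n: int,
) -> float:
    """Symmetrised between-replicate reproducibility at read cutoff ``n``.

    Junction identity is (chrom, start, end, strand).  Presence in the other
    replicate means >= 1 unique read there, regardless of the cutoff.
    """
    if n < 1:
        raise ValueError("cutoff must be >= 1")
    keys_a = {j.key for j in rep_a if j.unique_reads >= 1}
    keys_b = {j.key for j in rep_b if j.unique_reads >= 1}
    elig_a = {j.key for j in rep_a if j.unique_reads >= n}
    elig_b = {j.key for j in rep_b if j.unique_reads >= n}

    rates = []
    for elig, other in ((elig_a, keys_b), (elig_b, keys_a)):
        if elig:
            hits, total = _directional(elig, other)
            rates.append(hits / total)
    if not rates:
        raise NoJunctionsAtCutoff(f"no junctions with >= {n} unique reads")
    return sum(rates) / len(rates)


def choose_support_cutoff(
    rep_a: Sequence[SpliceJunction],
    rep_b: Sequence[SpliceJunction],
    threshold: float = 0.90,
    n_max: int = 50,
    sample_id: str = "",
) -> NpidrCurve:
    """Scan cutoffs n = 1, 2, ... until reproducibility exceeds ``threshold``.

    Returns the full evaluated curve; raises :class:`CutoffUnreachable` (with
    the best point attained) if no n <= n_max qualifies.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    values: dict[int, float] = {}
    best_n, best_value = 0, -1.0
    for n in range(1, n_max + 1):
        try:
            v = npidr_at_cutoff(rep_a, rep_b, n)
        except NoJunctionsAtCutoff:
            break
        values[n] = v
        if v > best_value:
            best_n, best_value = n, v
        if v > threshold:
            return NpidrCurve(sample_id, values, chosen_cutoff=n, threshold=threshold)
    raise CutoffUnreachable(sample_id, best_n, best_value)
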