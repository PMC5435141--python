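"""IRE1 cleavage-consensus scanning and enrichment.

IRE1, the stress-activated endonuclease that excises the 26-nt intron from
the XBP1 mRNA, cleaves at CUGCAG-like hexamers.  Five DNA-alphabet variants
are sought (the consensus plus known single-base variants)::

    CTGCAG  CCGCAG  CAGCAG  CTGCCG  CTGCAA

Scanning is on the transcribed strand only (the antisense strand is not an
IRE1 substrate), over the intron plus its 10-nt exonic flanks.  Each hit is
located by the signed distance of its 5' base to the nearer exon/intron
boundary (0 = at the boundary, positive = intronic side, negative = exonic
side).  Enrichment of total hit counts is tested against a uniform-base
binomial null with per-position success probability 5/4096.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

IRE1_HEXAMERS = ("CTGCAG", "CCGCAG", "CAGCAG", "CTGCCG", "CTGCAA")

#: per-position probability that a uniform random hexamer is one of the five
#: (they are distinct, so the probabilities simply add)
NULL_SITE_PROBABILITY = len(IRE1_HEXAMERS) / 4 ** 6


@dataclass(frozen=True, slots=True)
class MotifHit:
    intron_id: str
    motif: str
    position: int  # 0-based offset of the hexamer's 5' base in the flanked seq
    min_boundary_distance: int


def scan_ire1(
    flanked_seq: str,
    intron_bounds: tuple[int, int],
    intron_id: str = "",
) -> list[MotifHit]:
    """All IRE1-consensus occurrences in a flanked intron sequence.

    ``intron_bounds`` gives the offsets of the first and last intronic base
    within ``flanked_seq`` (with the default 10-nt flanks: (10, 10 + L - 1)).
    Overlapping occurrences are all reported.  The distance of a hit at
    offset p is ``p - b5`` to the 5' boundary and ``b3 - p`` to the 3'
    boundary (positive = intronic side); the smaller in absolute value is
    kept, ties going to the 5' boundary.
    """
    seq = flanked_seq.upper()
    b5, b3 = intron_bounds
    hits: list[MotifHit] = []
    for p in range(len(seq) - 5):
        hexamer = seq[p : p + 6]
        if "N" in hexamer or hexamer not in IRE1_HEXAMERS:
            continue
        d5 = p - b5
        d3 = b3 - p
        dist = d5 if abs(d5) <= abs(d3) else d3
        hits.append(MotifHit(intron_id, hexamer, p, dist))
    return hits


def boundary_distance_histogram(
    hits: Iterable[MotifHit], max_abs_distance: int | None = None
) -> tuple[dict[int, int], int]:
    """Counts of hits per signed boundary distance.

    Returns (histogram, n_at_boundary) where ``n_at_boundary`` is the number
    of hits at or within 1 nt of an exon/intron boundary.  Distances beyond
    ``max_abs_distance`` (if given) are dropped from the histogram but still
    counted toward the boundary tally when they qualify (they cannot).
    """
    hist: dict[int, int] = {}
    near = 0
    for hit in hits:
        d = hit.min_boundary_distance
        if abs(d) <= 1:
            near += 1
        if max_abs_distance is None or abs(d) <= max_abs_distance:
            hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items())), near


def enrichment_test(
    observed_count: int, searched_positions: int
) -> tuple[float, float]:
    """Upper-tail binomial test of hit-count enrichment.

    ``searched_positions`` is the total number of scannable hexamer start
    positions across the pool (length - 5 per sequence).  Returns
    (expected_count, p_value) with expected = positions * 5/4096 and
    p = P(X >= observed) under Binomial(positions, 5/4096); above 1e5
    positions the Poisson limit is used.
    """
    if searched_positions <= 0:
        raise ValueError("searched_positions must be positive")
    if observed_count < 0 or observed_count > searched_positions:
        raise ValueError("observed count outside [0, searched_positions]")
    expected = searched_positions * NULL_SITE_PROBABILITY
    if searched_positions > 1e5:
        p = float(stats.poisson.sf(observed_count - 1, expected))
    else:
        p = float(
            stats.binom.sf(observed_count - 1, searched_positions, NULL_SITE_PROBABILITY)
        )
    return expected, p


def scan_pool(records, flank: int = 10):
    """Scan every record's flanked sequence; return (hits, searched_positions)."""
    hits: list[MotifHit] = []
    searched = 0
    for rec in records:
        seq = rec.flanked_seq
        if len(seq) < 6:
            continue
        searched += len(seq) - 5
        bounds = (flank, flank + rec.length - 1)
        hits.extend(scan_ire1(seq, bounds, intron_id=rec.intron_id))
    return hits, searched
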