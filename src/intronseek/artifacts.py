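"""Screens for spontaneous genomic deletions masquerading as introns.

Small deletions arise preferentially in three sequence contexts, and a
deletion aligned against the reference genome is indistinguishable from a
spliced-out intron.  Candidates are therefore flagged when their sequence
context matches a deletion-prone pattern:

* **direct repeat** — the junction-proximal 6-mer of a flanking exon equals
  the corresponding terminal 6-mer of the intron (replication slippage
  between the repeat copies deletes the intervening sequence);
* **inverted repeat** — the first six intronic bases are the antiparallel
  reverse complement of the last six (the unwound DNA can form a stem-loop
  that is bypassed by the polymerase);
* **simple repeat** — more than 75% of the intron is covered by tandem
  copies of a single 1-5 nt unit (microsatellite instability).

All comparisons are exact and case-insensitive; an ``N`` never matches.
Sequences are given in transcribed orientation; every rule is
strand-symmetric under that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from .junctions import reverse_complement


@dataclass(frozen=True, slots=True)
class ArtifactFlags:
    direct_repeat: bool = False
    inverted_repeat: bool = False
    simple_repeat: bool = False

    @property
    def any(self) -> bool:
        return self.direct_repeat or self.inverted_repeat or self.simple_repeat


def _match(a: str, b: str) -> bool:
    """Exact match; N on either side disqualifies."""
    return "N" not in a and "N" not in b and a == b


def screen_direct_repeat(flank5: str, intron: str, flank3: str) -> bool:
    """Junction-proximal 6-mer identity between a flank and the intron end.

    True iff the last six bases of the 5' flanking exon equal the last six
    bases of the intron, or the first six bases of the 3' flanking exon equal
    the first six bases of the intron.
    """
    if len(flank5) < 6 or len(flank3) < 6:
        raise ValueError("flanks must be at least 6 nt")
    if len(intron) < 6:
        raise ValueError("intron must be at least 6 nt")
    flank5, intron, flank3 = flank5.upper(), intron.upper(), flank3.upper()
    return _match(flank5[-6:], intron[-6:]) or _match(flank3[:6], intron[:6])


def screen_inverted_repeat(intron: str) -> bool:
    """True iff the intron's first 6 nt reverse-complement its last 6 nt.

    For 10-11 nt introns the two terminal 6-mers overlap; they are still
    compared.
    """
    if len(intron) < 6:
        raise ValueError("intron must be at least 6 nt")
    intron = intron.upper()
    head, tail = intron[:6], intron[-6:]
    if "N" in head or "N" in tail:
        return False
    return reverse_complement(head) == tail


def _tandem_coverage(seq: str, k: int) -> float:
    """Max fraction of ``seq`` covered by tandem runs of any single k-mer.

    A run is >= 2 consecutive whole copies of the unit; runs of the same unit
    anywhere in the sequence are pooled (overlapping phases merged).
    """
    n = len(seq)
    covered: dict[str, set[int]] = {}
    for i in range(n - 2 * k + 1):
        unit = seq[i : i + k]
        if "N" in unit:
            continue
        j = i + k
        copies = 1
        while seq[j : j + k] == unit:
            copies += 1
            j += k
        if copies >= 2:
            covered.setdefault(unit, set()).update(range(i, i + copies * k))
    if not covered:
        return 0.0
    return max(len(pos) for pos in covered.values()) / n


def screen_simple_repeat(intron: str, max_unit: int = 5, fraction: float = 0.75) -> bool:
    """True iff >75% of the intron is a single-unit tandem repeat.

    Unit sizes 1-5 are tested.  For unit size 1 the criterion is plain base
    frequency (e.g. 8 A's in a 10-nt intron); for larger units it is the
    maximal coverage by tandem runs of one unit.  The threshold is strict.
    """
    intron = intron.upper()
    n = len(intron)
    if n == 0:
        return False
    best = max(intron.count(b) for b in "ACGT") / n
    for k in range(2, max_unit + 1):
        if n >= 2 * k:
            best = max(best, _tandem_coverage(intron, k))
        if best > fraction:
            return True
    return best > fraction


def screen_all(flank5: str, intron: str, flank3: str) -> ArtifactFlags:
    return ArtifactFlags(
        direct_repeat=screen_direct_repeat(flank5, intron, flank3),
        inverted_repeat=screen_inverted_repeat(intron),
        simple_repeat=screen_simple_repeat(intron),
    )


def apply_artifact_screens(records):
    """Partition records into (kept, removed); removed carry their flags.

    Records must expose ``flank5``, ``intron_seq`` and ``flank3`` attributes;
    each record's ``artifact`` field is set to its flags.  A record matching
    several screens appears once in the removed list with all flags set.
    """
    kept, removed = [], []
    for rec in records:
        flags = screen_all(rec.flank5, rec.intron_seq, rec.flank3)
        rec.artifact = flags
        (removed if flags.any else kept).append(rec)
    return kept, removed
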