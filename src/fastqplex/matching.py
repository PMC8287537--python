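"""Mismatch-tolerant barcode assignment via a precomputed best-match table.

Matching hundreds of millions of reads against a barcode set one read at a
time wastes work: there are only ``5^L`` possible length-``L`` windows over
``{A,C,G,T,N}``. So the best-match decision is computed once per *candidate
window* rather than once per read: enumerate every candidate, score it
against every barcode at the barcode-base offsets (UMI positions are
ignored), and store the outcome — unique best match, ambiguous tie, or no
match within the mismatch budget — in a dictionary. Per-read assignment is
then a single O(1) lookup of the read's barcode window.

The distance is positional (Hamming) over barcode offsets only; an ``N`` in
the read at a barcode offset counts as a mismatch to every defined base, so
N-containing reads can still be rescued within the mismatch budget. Reads
tying two or more barcodes at the minimal distance are discarded as
ambiguous.

For long windows where full enumeration would be too large, the table is
built lazily: windows are scored on first sight and memoized, with identical
semantics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

from .barcodes import BarcodePattern, Side

ALPHABET = "ACGTN"
_ALPHASET = frozenset(ALPHABET)

#: Largest 5^L for which the table is fully enumerated up front; longer
#: windows fall back to memoized on-demand scoring (same outcomes).
DEFAULT_FULL_TABLE_CAP = 5**7


class MatchStatus(Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    NONE = "none"


@dataclass(frozen=True)
class MatchOutcome:
    """Result of matching one candidate window against a barcode family.

    ``entry_id`` indexes the matched pattern within the family and is valid
    iff ``status`` is UNIQUE. ``mismatches`` is the minimal distance found
    (set for UNIQUE and AMBIGUOUS).
    """

    status: MatchStatus
    entry_id: int | None = None
    mismatches: int | None = None


NO_MATCH = MatchOutcome(MatchStatus.NONE)


def enumerate_candidates(length: int) -> Iterator[str]:
    """Yield every string of `length` over {A,C,G,T,N}, each exactly once."""
    if length < 1:
        raise ValueError(f"candidate length must be >= 1, got {length}")
    for tup in itertools.product(ALPHABET, repeat=length):
        yield "".join(tup)


def _mismatches(window: str, offsets: tuple[int, ...], core: str) -> int:
    # offsets may be negative (end-anchored 3' windows)
    mm = 0
    for off, base in zip(offsets, core):
        if window[off] != base:
            mm += 1
    return mm


def count_mismatches(candidate: str, pattern: BarcodePattern) -> int:
    """Positional mismatches between `candidate` and `pattern` at barcode offsets.

    UMI (``N``) positions of the pattern never count; an ``N`` in the
    candidate at a barcode offset counts as one mismatch.
    """
    if len(candidate) != len(pattern.raw):
        raise ValueError(
            f"candidate length {len(candidate)} != pattern length {len(pattern.raw)}"
        )
    return _mismatches(candidate, pattern.anchor_offsets(), pattern.core)


def best_match(
    candidate: str,
    patterns: Sequence[BarcodePattern],
    max_mismatches: int,
) -> MatchOutcome:
    """Best-match outcome of `candidate` over a compatible pattern family.

    UNIQUE iff exactly one pattern attains the minimal mismatch count and
    that count is within `max_mismatches`; AMBIGUOUS iff two or more tie at
    a minimal count within budget; NONE otherwise. The candidate must cover
    every pattern's barcode offsets (equal-length, or the shared anchored
    window).
    """
    if not patterns:
        raise ValueError("no barcode patterns given")
    counts = [_mismatches(candidate, p.anchor_offsets(), p.core) for p in patterns]
    best = min(counts)
    if best > max_mismatches:
        return NO_MATCH
    ties = counts.count(best)
    if ties > 1:
        return MatchOutcome(MatchStatus.AMBIGUOUS, None, best)
    return MatchOutcome(MatchStatus.UNIQUE, counts.index(best), best)


class MatchIndex:
    """Precomputed candidate-window → :class:`MatchOutcome` table for one family.

    One index serves one barcode family: the sheet's 5' patterns, or one
    entry's linked 3' patterns. The key window is the prefix through the last
    barcode base (5' side) or the end-anchored window back to the first
    barcode base (3' side); the matched pattern's own full length governs
    slicing and UMI extraction downstream, so patterns with different UMI
    lengths share one index.
    """

    def __init__(
        self,
        patterns: Sequence[BarcodePattern],
        max_mismatches: int,
        full_table_cap: int = DEFAULT_FULL_TABLE_CAP,
    ) -> None:
        patterns = tuple(patterns)
        if not patterns:
            raise ValueError("cannot build an index over zero patterns")
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        sides = {p.side for p in patterns}
        if len(sides) != 1:
            raise ValueError("patterns in one index must share a side")
        offsets = {p.anchor_offsets() for p in patterns}
        if len(offsets) != 1:
            raise ValueError(
                "patterns in one index must share barcode-base offsets "
                f"(got {sorted(offsets)})"
            )
        self.patterns = patterns
        self.side = patterns[0].side
        self.core_offsets = patterns[0].anchor_offsets()
        self.max_mismatches = max_mismatches
        if self.side is Side.FIVE_PRIME:
            self.key_length = max(self.core_offsets) + 1
        else:
            self.key_length = -min(self.core_offsets)
        self._eager = 5**self.key_length <= full_table_cap
        self._table: dict[str, MatchOutcome] = {}
        if self._eager:
            for cand in enumerate_candidates(self.key_length):
                self._table[cand] = best_match(cand, patterns, max_mismatches)

    @property
    def table(self) -> dict[str, MatchOutcome]:
        """The underlying map (complete only when eagerly enumerated)."""
        return self._table

    @property
    def is_fully_enumerated(self) -> bool:
        return self._eager

    def lookup(self, window: str) -> MatchOutcome:
        """Best-match outcome for a read's barcode window, in O(1).

        Characters outside ``{A,C,G,T,N}`` at a barcode offset give NONE;
        elsewhere (UMI positions) they are irrelevant and treated as ``N``.
        """
        if len(window) != self.key_length:
            raise ValueError(
                f"window length {len(window)} != index key length {self.key_length}"
            )
        out = self._table.get(window)
        if out is not None:
            return out
        for off in self.core_offsets:
            if window[off] not in _ALPHASET:
                return NO_MATCH
        key = "".join(c if c in _ALPHASET else "N" for c in window)
        if self._eager:
            return self._table[key]
        out = best_match(key, self.patterns, self.max_mismatches)
        self._table[key] = out
        if key != window:
            self._table[window] = out
        return out


def build_index(
    patterns: Sequence[BarcodePattern],
    max_mismatches: int,
    full_table_cap: int = DEFAULT_FULL_TABLE_CAP,
) -> MatchIndex:
    """Build the best-match lookup table for one compatible barcode family."""
    return MatchIndex(patterns, max_mismatches, full_table_cap)
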