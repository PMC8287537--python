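"""Barcode patterns and the sample-sheet CSV dialect.

A barcode *pattern* is a string over ``{A, C, G, T, N}``. Defined bases are
the barcode proper — they identify the sample. ``N`` positions are randomers
(unique molecular identifiers, UMIs) whose per-read instantiation is recorded
so PCR duplicates can be collapsed after alignment. A 5' pattern is anchored
at the start of the forward read; a 3' pattern is anchored at the read's 3'
end (its last character aligns with the last retained base of the insert).

The sample sheet is a comma-separated file, one entry per line: the first
field is the 5' pattern, any further fields are 3' patterns linked to it
(combinatorial barcoding — a sample is the unique *pair* of 5' and 3'
barcodes). Any field may carry a ``:name`` suffix naming that sample, except
a 5' pattern that has linked 3' patterns, whose name would be ambiguous.

Compatibility rules enforced here: every 5' pattern in a sheet must place its
barcode bases at identical offsets from the 5' end; within one entry, all 3'
patterns must place theirs at identical offsets from the 3' end. 3' sets
belonging to *different* 5' barcodes are independent. UMI stretches may
differ in length between patterns, so total pattern lengths may differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

_ALPHABET = frozenset("ACGTN")


class Side(Enum):
    """Which read end a pattern is anchored to."""

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


class BarcodeError(ValueError):
    """Malformed barcode pattern or invalid/incompatible sample sheet."""


@dataclass(frozen=True)
class BarcodePattern:
    """One barcode string with its UMI-position mask.

    Attributes
    ----------
    raw:
        The pattern as written, upper-cased (e.g. ``"NNNATGCNN"``).
    side:
        Anchoring end.
    barcode_positions:
        0-based offsets into ``raw`` holding defined bases.
    umi_positions:
        0-based offsets into ``raw`` holding ``N``.
    core:
        The defined bases only, in order (e.g. ``"ATGC"``).
    """

    raw: str
    side: Side
    barcode_positions: tuple[int, ...]
    umi_positions: tuple[int, ...]
    core: str

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def end_anchored_offsets(self) -> tuple[int, ...]:
        """Barcode offsets relative to the pattern's end (negative values)."""
        n = len(self.raw)
        return tuple(p - n for p in self.barcode_positions)

    def anchor_offsets(self) -> tuple[int, ...]:
        """Offsets usable to index a read slice anchored at this side.

        5' patterns give non-negative offsets from the slice start; 3'
        patterns give negative offsets from the slice end (valid Python
        negative indices into an end-anchored window).
        """
        if self.side is Side.FIVE_PRIME:
            return self.barcode_positions
        return self.end_anchored_offsets

    @property
    def umi_length(self) -> int:
        return len(self.umi_positions)


def parse_pattern(text: str, side: Side) -> BarcodePattern:
    """Parse one barcode pattern string.

    Case-insensitive; upper-cased on ingest. Raises :class:`BarcodeError` on
    characters outside ``{A,C,G,T,N}`` (naming the offending position) and on
    all-``N`` patterns, which contain no barcode bases.
    """
    if not text or not text.strip():
        raise BarcodeError("empty barcode pattern")
    raw = text.strip().upper()
    for i, ch in enumerate(raw):
        if ch not in _ALPHABET:
            raise BarcodeError(
                f"invalid character {ch!r} at position {i} in barcode pattern {raw!r}"
            )
    barcode_positions = tuple(i for i, ch in enumerate(raw) if ch != "N")
    if not barcode_positions:
        raise BarcodeError(f"pattern {raw!r} has no barcode bases (all N)")
    umi_positions = tuple(i for i, ch in enumerate(raw) if ch == "N")
    core = "".join(raw[i] for i in barcode_positions)
    return BarcodePattern(raw, side, barcode_positions, umi_positions, core)


def render(pattern: BarcodePattern) -> str:
    """Inverse of :func:`parse_pattern` (modulo case normalisation)."""
    return pattern.raw


@dataclass(frozen=True)
class SheetEntry:
    """One sample-sheet line: a 5' pattern with its linked 3' patterns.

    ``five_prime_name`` is set iff the entry has no linked 3' patterns;
    otherwise ``three_prime_names`` names each (5', 3') sample pair.
    """

    five_prime: BarcodePattern
    three_primes: tuple[BarcodePattern, ...]
    five_prime_name: str | None
    three_prime_names: tuple[str, ...]

    @property
    def sample_names(self) -> tuple[str, ...]:
        if self.three_primes:
            return self.three_prime_names
        assert self.five_prime_name is not None
        return (self.five_prime_name,)

    @property
    def no_three_prime_match_name(self) -> str:
        """Routing name for reads matching this 5' barcode but no 3' barcode."""
        return f"5bc_{self.five_prime.core}_no3bc"


@dataclass(frozen=True)
class SampleSheet:
    """A validated set of sheet entries sharing compatible 5' barcodes."""

    entries: tuple[SheetEntry, ...]

    @property
    def five_prime_core_offsets(self) -> tuple[int, ...]:
        return self.entries[0].five_prime.barcode_positions

    @property
    def five_prime_core_length(self) -> int:
        return len(self.five_prime_core_offsets)

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(n for e in self.entries for n in e.sample_names)

    @property
    def five_prime_patterns(self) -> tuple[BarcodePattern, ...]:
        return tuple(e.five_prime for e in self.entries)


def _split_field(field: str) -> tuple[str, str | None]:
    pattern_text, _, name = field.partition(":")
    name = name.strip()
    return pattern_text.strip(), (name or None)


def parse_sample_sheet(csv_text: str) -> SampleSheet:
    """Parse and validate a barcode CSV.

    One entry per non-empty line. The first comma-separated field is the 5'
    pattern; further fields are its linked 3' patterns. A ``:name`` suffix on
    a field names that sample; unnamed samples get deterministic auto names:
    ``5bc_<core>`` for 5'-only entries, ``5bc_<5core>_3bc_<3core>`` for
    combinatorial ones. Windows line endings and surrounding whitespace are
    tolerated.

    Raises :class:`BarcodeError` for: 5' patterns whose barcode-base offsets
    disagree between lines; 3' patterns whose end-anchored offsets disagree
    within a line; duplicate 5' cores; duplicate 3' cores within an entry; a
    name attached to a 5' pattern that has linked 3' patterns; duplicate
    sample names anywhere.
    """
    entries: list[SheetEntry] = []
    ref_offsets: tuple[int, ...] | None = None
    ref_line = -1
    seen_five_cores: dict[str, int] = {}
    for lineno, line in enumerate(csv_text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split(",")]
        p5_text, p5_name = _split_field(fields[0])
        five = parse_pattern(p5_text, Side.FIVE_PRIME)
        if ref_offsets is None:
            ref_offsets, ref_line = five.barcode_positions, lineno
        elif five.barcode_positions != ref_offsets:
            raise BarcodeError(
                "incompatible 5' barcodes: line "
                f"{ref_line} places barcode bases at offsets {ref_offsets} "
                f"but line {lineno} ({five.raw!r}) at {five.barcode_positions}"
            )
        if five.core in seen_five_cores:
            raise BarcodeError(
                f"duplicate 5' barcode core {five.core!r} on lines "
                f"{seen_five_cores[five.core]} and {lineno}"
            )
        seen_five_cores[five.core] = lineno

        three_fields = [f for f in fields[1:] if f]
        if three_fields and p5_name is not None:
            raise BarcodeError(
                f"line {lineno}: 5' barcode {five.raw!r} has linked 3' barcodes "
                "and cannot carry a sample name (assignment would be ambiguous)"
            )
        threes: list[BarcodePattern] = []
        names3: list[str] = []
        t_ref: tuple[int, ...] | None = None
        seen_three_cores: set[str] = set()
        for field in three_fields:
            t_text, t_name = _split_field(field)
            pat = parse_pattern(t_text, Side.THREE_PRIME)
            if t_ref is None:
                t_ref = pat.end_anchored_offsets
            elif pat.end_anchored_offsets != t_ref:
                raise BarcodeError(
                    f"incompatible 3' barcodes on line {lineno}: {pat.raw!r} "
                    "does not share end-anchored barcode offsets with its siblings"
                )
            if pat.core in seen_three_cores:
                raise BarcodeError(
                    f"duplicate 3' barcode core {pat.core!r} on line {lineno}"
                )
            seen_three_cores.add(pat.core)
            threes.append(pat)
            names3.append(t_name or f"5bc_{five.core}_3bc_{pat.core}")
        five_name = None if threes else (p5_name or f"5bc_{five.core}")
        entries.append(SheetEntry(five, tuple(threes), five_name, tuple(names3)))

    if not entries:
        raise BarcodeError("sample sheet contains no barcode entries")
    all_names = [n for e in entries for n in e.sample_names]
    seen: set[str] = set()
    for name in all_names:
        if name in seen:
            raise BarcodeError(f"duplicate sample name {name!r} in sheet")
        seen.add(name)
    return SampleSheet(tuple(entries))
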