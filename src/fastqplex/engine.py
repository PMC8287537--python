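"""Per-read transformation pipeline.

Each read (or read pair) flows through: 5' barcode detection → UMI capture →
3' adapter trimming → 3' quality trimming → 3' barcode detection (when the
matched 5' entry links 3' barcodes) → minimum-length filter. The captured
UMI bases are appended to the read identifier (``<id>_rbc:<UMI>`` before the
first whitespace) so downstream deduplicators can collapse PCR duplicates
after alignment.

Single-end combinatorial caveat: the 3' barcode sits at the far end of the
insert, so it is only present in the read when the insert is short enough
for the sequencer to read through into the adapter. To avoid calling 3'
barcodes on reads that merely *end* near barcode-like sequence, a 3' barcode
is only assigned when at least ``min_overlap_for_3bc`` (default 3) bases of
the sequencing adapter were detected and trimmed — evidence that the read's
end is the true insert end. In paired mode the 3' barcode is instead read
directly off the start of the reverse read (reverse-complemented), with no
adapter gate.

Coordinates are 0-based half-open; qualities are Phred+33 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .barcodes import BarcodePattern, SampleSheet, Side, parse_pattern
from .matching import (
    DEFAULT_FULL_TABLE_CAP,
    MatchIndex,
    MatchOutcome,
    MatchStatus,
    NO_MATCH,
    build_index,
)

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # Illumina universal, forward read

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedReadError(ValueError):
    """Sequence and quality strings disagree in length."""


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record: identifier (without '@'), sequence, Phred+33 quality."""

    identifier: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class TrimConfig:
    """Tunable thresholds for trimming and barcode detection.

    ``m5``/``m3`` are the mismatch budgets for 5'/3' barcode detection.
    ``min_overlap_trim`` is the smallest adapter suffix-overlap the trimmer
    accepts; ``min_overlap_for_3bc`` is the adapter evidence (trimmed bases)
    required before a single-end 3' barcode may be assigned.
    """

    adapter_fwd: str = DEFAULT_ADAPTER
    adapter_rev: str = DEFAULT_ADAPTER
    quality_threshold: int = 20
    min_overlap_trim: int = 3
    min_overlap_for_3bc: int = 3
    max_adapter_error_rate: float = 0.1
    min_length: int = 20
    m5: int = 1
    m3: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.max_adapter_error_rate < 1):
            raise ValueError("max_adapter_error_rate must be in [0, 1)")
        for name in (
            "quality_threshold",
            "min_overlap_trim",
            "min_overlap_for_3bc",
            "min_length",
            "m5",
            "m3",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class Category(Enum):
    ASSIGNED = "assigned"
    FIVE_ONLY_AWAITING_3BC = "five_only_awaiting_3bc"
    NO_MATCH = "no_match"
    TOO_SHORT = "too_short"


@dataclass(frozen=True)
class DemuxOutcome:
    """Per-read result: routing category, sample, UMI, trimmed record(s)."""

    category: Category
    sample_name: str | None
    umi: str
    output_record: ReadRecord
    adapter_bases_removed: int
    mate_record: ReadRecord | None = None


@dataclass(frozen=True)
class DemuxIndexes:
    """The lookup tables for one run: one 5' index, one 3' index per entry."""

    five: MatchIndex
    three: tuple[MatchIndex | None, ...]
    paired: bool = False


def _reverse_complement_pattern(pattern: BarcodePattern) -> BarcodePattern:
    # N maps to N, so UMI positions mirror cleanly.
    return parse_pattern(reverse_complement(pattern.raw), Side.FIVE_PRIME)


def build_indexes(
    sheet: SampleSheet,
    m5: int,
    m3: int,
    paired: bool = False,
    full_table_cap: int = DEFAULT_FULL_TABLE_CAP,
) -> DemuxIndexes:
    """Build all lookup tables a demultiplexing run needs.

    In paired mode each entry's 3' patterns are reverse-complemented and
    anchored at the reverse read's start, where the 3' barcode physically
    appears.
    """
    five = build_index(sheet.five_prime_patterns, m5, full_table_cap)
    threes: list[MatchIndex | None] = []
    for entry in sheet.entries:
        if not entry.three_primes:
            threes.append(None)
        elif paired:
            rc = [_reverse_complement_pattern(p) for p in entry.three_primes]
            threes.append(build_index(rc, m3, full_table_cap))
        else:
            threes.append(build_index(entry.three_primes, m3, full_table_cap))
    return DemuxIndexes(five, tuple(threes), paired)


def detect_5prime(
    read: ReadRecord, index: MatchIndex, sheet: SampleSheet
) -> tuple[MatchOutcome, str, ReadRecord]:
    """Match the read's 5' window; on success, capture the UMI and strip the prefix.

    Returns ``(outcome, umi5, remainder)``. Reads shorter than the index
    window (or than the matched pattern's full length) yield NONE untouched.
    """
    seq = read.sequence
    if len(seq) < index.key_length:
        return NO_MATCH, "", read
    out = index.lookup(seq[: index.key_length])
    if out.status is not MatchStatus.UNIQUE:
        return out, "", read
    assert out.entry_id is not None
    pattern = sheet.entries[out.entry_id].five_prime
    plen = len(pattern)
    if len(seq) < plen:
        return NO_MATCH, "", read
    umi5 = "".join(seq[i] for i in pattern.umi_positions)
    remainder = ReadRecord(read.identifier, seq[plen:], read.quality[plen:])
    return out, umi5, remainder


def trim_adapter(
    seq: str, qual: str, adapter: str, cfg: TrimConfig
) -> tuple[str, str, int]:
    """Remove the 3' sequencing adapter (and everything after it).

    Semi-global, mismatch-only scan: the leftmost position where the adapter
    (or an adapter prefix overhanging the read's 3' end) matches with an
    error fraction <= ``max_adapter_error_rate`` over an overlap >=
    ``min_overlap_trim`` wins; the read is cut at that position. Returns
    ``(seq, qual, bases_removed)`` with ``bases_removed == 0`` when no
    admissible occurrence exists.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    n = len(seq)
    alen = len(adapter)
    rate = cfg.max_adapter_error_rate
    for start in range(0, n - cfg.min_overlap_trim + 1):
        overlap = alen if alen <= n - start else n - start
        allowed = int(rate * overlap)
        mm = 0
        for i in range(overlap):
            if seq[start + i] != adapter[i]:
                mm += 1
                if mm > allowed:
                    break
        else:
            return seq[:start], qual[:start], n - start
    return seq, qual, 0


def quality_trim(seq: str, qual: str, threshold: int) -> tuple[str, str]:
    """3'-end quality trim by the BWA-style running-sum rule.

    Scanning from the 3' end, accumulate ``threshold - phred(base)``; cut at
    the position where the running sum is maximal, stopping once it goes
    negative. Threshold 0 is the identity.
    """
    if threshold <= 0:
        return seq, qual
    s = 0
    max_s = 0
    cut = len(qual)
    for i in range(len(qual) - 1, -1, -1):
        s += threshold - (ord(qual[i]) - 33)
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    return seq[:cut], qual[:cut]


def detect_3prime_single_end(
    remainder: ReadRecord,
    entry_index: MatchIndex,
    adapter_bases_removed: int,
    cfg: TrimConfig,
) -> tuple[MatchOutcome, str, ReadRecord]:
    """Match the 3' barcode at the end of an adapter/quality-trimmed read.

    Gated on adapter evidence: if fewer than ``min_overlap_for_3bc`` adapter
    bases were trimmed, no 3' window is even attempted (the read's end is not
    known to be the insert's end). On a unique match the matched pattern's
    full length is stripped from the 3' end and its UMI bases captured.
    """
    if adapter_bases_removed < cfg.min_overlap_for_3bc:
        return NO_MATCH, "", remainder
    seq = remainder.sequence
    if len(seq) < entry_index.key_length:
        return NO_MATCH, "", remainder
    out = entry_index.lookup(seq[-entry_index.key_length :])
    if out.status is not MatchStatus.UNIQUE:
        return out, "", remainder
    assert out.entry_id is not None
    pattern = entry_index.patterns[out.entry_id]
    plen = len(pattern)
    if len(seq) < plen:
        return NO_MATCH, "", remainder
    window = seq[-plen:]
    umi3 = "".join(window[i] for i in pattern.umi_positions)
    final = ReadRecord(remainder.identifier, seq[:-plen], remainder.quality[:-plen])
    return out, umi3, final


def detect_3prime_paired(
    mate: ReadRecord, entry_index: MatchIndex, cfg: TrimConfig
) -> tuple[MatchOutcome, str, ReadRecord]:
    """Match the 3' barcode at the start of the reverse read.

    The reverse read begins with the reverse complement of the 3' barcode
    region; `entry_index` was built over reverse-complemented patterns. On a
    unique match the prefix is stripped from the mate and the UMI returned in
    forward-strand orientation.
    """
    seq = mate.sequence
    if len(seq) < entry_index.key_length:
        return NO_MATCH, "", mate
    out = entry_index.lookup(seq[: entry_index.key_length])
    if out.status is not MatchStatus.UNIQUE:
        return out, "", mate
    assert out.entry_id is not None
    rc_pattern = entry_index.patterns[out.entry_id]
    plen = len(rc_pattern)
    if len(seq) < plen:
        return NO_MATCH, "", mate
    forward = reverse_complement(seq[:plen])
    # forward-strand UMI offsets are the mirrored rc-pattern UMI offsets
    fwd_umi_positions = sorted(plen - 1 - q for q in rc_pattern.umi_positions)
    umi3 = "".join(forward[i] for i in fwd_umi_positions)
    trimmed = ReadRecord(mate.identifier, seq[plen:], mate.quality[plen:])
    return out, umi3, trimmed


def append_umi(identifier: str, umi: str) -> str:
    """Insert ``_rbc:<umi>`` before the identifier's first whitespace."""
    if not umi:
        return identifier
    cut = next(
        (i for i, c in enumerate(identifier) if c.isspace()), len(identifier)
    )
    return f"{identifier[:cut]}_rbc:{umi}{identifier[cut:]}"


def _check_record(read: ReadRecord) -> None:
    if len(read.sequence) != len(read.quality):
        raise MalformedReadError(
            f"record {read.identifier!r}: sequence length {len(read.sequence)} "
            f"!= quality length {len(read.quality)}"
        )


def process_read(
    read: ReadRecord,
    sheet: SampleSheet,
    indexes: DemuxIndexes,
    cfg: TrimConfig,
) -> DemuxOutcome:
    """Run one single-end read through the full pipeline."""
    _check_record(read)
    out5, umi5, rem = detect_5prime(read, indexes.five, sheet)
    if out5.status is not MatchStatus.UNIQUE:
        return DemuxOutcome(Category.NO_MATCH, None, "", read, 0)
    assert out5.entry_id is not None
    entry = sheet.entries[out5.entry_id]
    seq, qual, removed = trim_adapter(rem.sequence, rem.quality, cfg.adapter_fwd, cfg)
    seq, qual = quality_trim(seq, qual, cfg.quality_threshold)
    rem = ReadRecord(rem.identifier, seq, qual)
    umi = umi5
    if entry.three_primes:
        out3, umi3, final = detect_3prime_single_end(
            rem, indexes.three[out5.entry_id], removed, cfg
        )
        if out3.status is MatchStatus.UNIQUE:
            assert out3.entry_id is not None
            category = Category.ASSIGNED
            sample = entry.three_prime_names[out3.entry_id]
            umi = umi5 + umi3
            rem = final
        else:
            category = Category.FIVE_ONLY_AWAITING_3BC
            sample = entry.no_three_prime_match_name
    else:
        category = Category.ASSIGNED
        sample = entry.five_prime_name
    if len(rem.sequence) < cfg.min_length:
        return DemuxOutcome(Category.TOO_SHORT, sample, umi, rem, removed)
    out_rec = ReadRecord(append_umi(rem.identifier, umi), rem.sequence, rem.quality)
    return DemuxOutcome(category, sample, umi, out_rec, removed)


def process_pair(
    read: ReadRecord,
    mate: ReadRecord,
    sheet: SampleSheet,
    indexes: DemuxIndexes,
    cfg: TrimConfig,
) -> DemuxOutcome:
    """Run one read pair through the pipeline.

    The forward read carries the 5' barcode; the reverse read carries the 3'
    barcode (reverse-complemented, at its start), so combinatorial assignment
    needs no adapter read-through. When a 3' barcode is assigned and the
    forward read's adapter was detected (same >= ``min_overlap_for_3bc``
    evidence as single-end), the matched 3' pattern length is also stripped
    from the forward read's end so barcode/UMI bases never reach the output.
    """
    _check_record(read)
    _check_record(mate)
    out5, umi5, rem = detect_5prime(read, indexes.five, sheet)
    if out5.status is not MatchStatus.UNIQUE:
        return DemuxOutcome(Category.NO_MATCH, None, "", read, 0, mate)
    assert out5.entry_id is not None
    entry = sheet.entries[out5.entry_id]
    seq, qual, removed = trim_adapter(rem.sequence, rem.quality, cfg.adapter_fwd, cfg)
    seq, qual = quality_trim(seq, qual, cfg.quality_threshold)
    rem = ReadRecord(rem.identifier, seq, qual)
    umi = umi5
    mate_work = mate
    if entry.three_primes:
        out3, umi3, mate_trimmed = detect_3prime_paired(
            mate, indexes.three[out5.entry_id], cfg
        )
        if out3.status is MatchStatus.UNIQUE:
            assert out3.entry_id is not None
            category = Category.ASSIGNED
            sample = entry.three_prime_names[out3.entry_id]
            umi = umi5 + umi3
            mate_work = mate_trimmed
            plen = len(entry.three_primes[out3.entry_id])
            if removed >= cfg.min_overlap_for_3bc and len(rem.sequence) >= plen:
                rem = ReadRecord(
                    rem.identifier, rem.sequence[:-plen], rem.quality[:-plen]
                )
        else:
            category = Category.FIVE_ONLY_AWAITING_3BC
            sample = entry.no_three_prime_match_name
    else:
        category = Category.ASSIGNED
        sample = entry.five_prime_name
    mseq, mqual, _ = trim_adapter(
        mate_work.sequence, mate_work.quality, cfg.adapter_rev, cfg
    )
    mseq, mqual = quality_trim(mseq, mqual, cfg.quality_threshold)
    mate_work = ReadRecord(mate_work.identifier, mseq, mqual)
    if len(rem.sequence) < cfg.min_length:
        return DemuxOutcome(Category.TOO_SHORT, sample, umi, rem, removed, mate_work)
    out_rec = ReadRecord(append_umi(rem.identifier, umi), rem.sequence, rem.quality)
    out_mate = ReadRecord(append_umi(mate_work.identifier, umi), mseq, mqual)
    return DemuxOutcome(category, sample, umi, out_rec, removed, out_mate)
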