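"""Synthetic sequencing lanes with known ground truth.

Each simulated molecule has the anatomy of an iCLIP / ribosome-profiling
library fragment: ``[5' UMI+barcode] [insert] [3' barcode+UMI, combinatorial
entries only]``. The forward read is the molecule followed by the sequencing
adapter and random post-adapter filler, truncated to the read length; when a
molecule is flagged *non-read-through* its insert is lengthened past the read
end, so neither the 3' barcode nor the adapter appears in the forward read.
Paired-end lanes additionally emit the mate: the reverse complement of the
molecule (so it begins with the reverse-complemented 3' barcode region),
followed by the reverse adapter and filler.

Every read is *certified*: inserts and fillers are rejection-sampled until
the adapter occurs at exactly the intended position — and nowhere earlier —
under the same semi-global scan the pipeline uses, and non-read-through
reads are guaranteed adapter-free. Zero-error lanes are therefore exactly
recoverable: the truth table is the unique correct answer, not merely the
overwhelmingly likely one. Sequencing errors, when requested, are injected
as substitutions *after* certification, independently per base within each
region (5' barcode core, 3' barcode core, insert).

Not emulated: indels, per-cycle Illumina error profiles, quality-dependent
errors, optical duplicates. Tests passing on these lanes demonstrate the
correctness of barcode logic and trimming bookkeeping, not robustness to
error modes outside the substitution model.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass

from .barcodes import BarcodePattern, SampleSheet, SheetEntry, parse_sample_sheet
from .engine import DEFAULT_ADAPTER, TrimConfig, reverse_complement, trim_adapter

_BASES = "ACGT"
_HIGH_QUAL = "I"  # Phred 40
_LOW_QUAL = "#"  # Phred 2
_MAX_RESAMPLE = 500
_CERT_MIN_OVERLAP = 3
_CERT_ERROR_RATE = 0.1


@dataclass(frozen=True)
class LaneSpec:
    """Study conditions for one simulated lane.

    ``fraction_no_adapter`` is the fraction of molecules whose insert is too
    long for the sequencer to read through into the adapter; in single-end
    mode such combinatorial reads cannot receive a 3' barcode.
    ``low_quality_tail`` replaces that many bases of quality at the 3' end of
    the forward read with Phred 2 to exercise quality trimming; when nonzero
    the truth table's ``expected_sequence`` ignores quality trimming.
    """

    sheet: SampleSheet
    reads_per_sample: int = 1000
    insert_length_range: tuple[int, int] = (25, 45)
    adapter: str = DEFAULT_ADAPTER
    adapter_rev: str = DEFAULT_ADAPTER
    error_rate_five_prime_core: float = 0.0
    error_rate_three_prime_core: float = 0.0
    error_rate_insert: float = 0.0
    fraction_no_adapter: float = 0.0
    read_length: int = 100
    seed: int = 0
    paired: bool = False
    low_quality_tail: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.insert_length_range
        if not (1 <= lo <= hi):
            raise ValueError("insert_length_range must satisfy 1 <= min <= max")
        for name in (
            "error_rate_five_prime_core",
            "error_rate_three_prime_core",
            "error_rate_insert",
            "fraction_no_adapter",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        max5 = max(len(e.five_prime) for e in self.sheet.entries)
        max3 = max(
            (len(p) for e in self.sheet.entries for p in e.three_primes), default=0
        )
        # read-through molecules must leave >= 3 adapter bases in the read
        if max5 + hi + max3 + _CERT_MIN_OVERLAP > self.read_length:
            raise ValueError(
                "insert length range incompatible with read length: "
                f"{max5} + {hi} + {max3} + {_CERT_MIN_OVERLAP} > {self.read_length}"
            )


@dataclass(frozen=True)
class TrueRead:
    """Ground truth for one simulated read (pair).

    ``sample_name`` is the routing bucket the pipeline should choose — a
    sample name, or an entry's no-3'-match bucket for non-read-through
    combinatorial reads in single-end mode. ``umi`` is the expected header
    UMI and ``expected_sequence`` the expected output sequence after all
    trimming. ``expected_mate_sequence`` is set in paired mode.
    """

    identifier: str
    sample_name: str
    umi: str
    expected_sequence: str
    read_through: bool
    expected_mate_sequence: str | None = None


def _instantiate(pattern: BarcodePattern, rng: random.Random) -> tuple[str, str]:
    """Fill a pattern's N positions with random bases; return (sequence, umi)."""
    chars = list(pattern.raw)
    for i in pattern.umi_positions:
        chars[i] = rng.choice(_BASES)
    seq = "".join(chars)
    umi = "".join(seq[i] for i in pattern.umi_positions)
    return seq, umi


def _random_seq(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _certified_cut(segment: str, adapter: str) -> int:
    """Bases kept when the pipeline's adapter scan runs on `segment`."""
    cfg = TrimConfig(
        adapter_fwd=adapter,
        min_overlap_trim=_CERT_MIN_OVERLAP,
        max_adapter_error_rate=_CERT_ERROR_RATE,
        min_length=0,
        quality_threshold=0,
    )
    trimmed, _, _ = trim_adapter(segment, _HIGH_QUAL * len(segment), adapter, cfg)
    return len(trimmed)


def _substitute(seq, positions, rate, rng):
    if rate <= 0.0:
        return seq
    chars = list(seq)
    for i in positions:
        if 0 <= i < len(chars) and rng.random() < rate:
            chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
    return "".join(chars)


def _sample_slots(sheet: SampleSheet):
    slots: list[tuple[SheetEntry, BarcodePattern | None, str]] = []
    for entry in sheet.entries:
        if entry.three_primes:
            for pat, name in zip(entry.three_primes, entry.three_prime_names):
                slots.append((entry, pat, name))
        else:
            assert entry.five_prime_name is not None
            slots.append((entry, None, entry.five_prime_name))
    return slots


def generate_lane(spec: LaneSpec):
    """Generate one lane.

    Returns ``(records, truth)`` where ``records`` is a list of
    ``(identifier, sequence, quality)`` tuples — in paired mode, of
    ``(forward_tuple, reverse_tuple)`` pairs — and ``truth`` is the parallel
    list of :class:`TrueRead`. Deterministic for a given spec.
    """
    rng = random.Random(spec.seed)
    records: list = []
    truth: list[TrueRead] = []
    serial = 0
    for entry, pat3, sample_name in _sample_slots(spec.sheet):
        for _ in range(spec.reads_per_sample):
            serial += 1
            rec, tr = _build_read(spec, rng, serial, entry, pat3, sample_name)
            records.append(rec)
            truth.append(tr)
    return records, truth


def _build_read(spec: LaneSpec, rng: random.Random, serial: int,
                entry: SheetEntry, pat3: BarcodePattern | None, sample_name: str):
    identifier = f"SIM:1:L1:{serial} 1:N:0:1"
    rl = spec.read_length
    lo, hi = spec.insert_length_range
    read_through = rng.random() >= spec.fraction_no_adapter
    inst5, umi5 = _instantiate(entry.five_prime, rng)
    inst3, umi3 = ("", "")
    if pat3 is not None:
        inst3, umi3 = _instantiate(pat3, rng)
    len5, len3 = len(inst5), len(inst3)

    for _ in range(_MAX_RESAMPLE):
        if read_through:
            insert = _random_seq(rng.randint(lo, hi), rng)
        else:
            # insert extends past the read end on both forward and mate
            insert = _random_seq(rl - len5 + rng.randint(1, 20), rng)
        molecule = inst5 + insert + inst3

        space_f = rl - len(molecule)
        if space_f > 0:
            filler = _random_seq(max(0, space_f - len(spec.adapter)), rng)
            forward = (molecule + spec.adapter + filler)[:rl]
        else:
            forward = molecule[:rl]
        expected_keep_f = (len(insert) + len3) if read_through else (rl - len5)
        if _certified_cut(forward[len5:], spec.adapter) != expected_keep_f:
            continue

        if spec.paired:
            rc = reverse_complement(molecule)
            space_m = rl - len(rc)
            if space_m > 0:
                mfiller = _random_seq(max(0, space_m - len(spec.adapter_rev)), rng)
                mate = (rc + spec.adapter_rev + mfiller)[:rl]
            else:
                mate = rc[:rl]
            expected_keep_m = (len(insert) + len5) if read_through else (rl - len3)
            if _certified_cut(mate[len3:], spec.adapter_rev) != expected_keep_m:
                continue
        else:
            mate = None
        break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not certify a simulated read")

    # truth: routing bucket, header UMI, expected output sequence(s)
    if pat3 is None:
        expected_sample, expected_umi = sample_name, umi5
        expected_seq = insert if read_through else insert[: rl - len5]
    elif spec.paired:
        expected_sample, expected_umi = sample_name, umi5 + umi3
        expected_seq = insert if read_through else insert[: rl - len5]
    elif read_through:
        expected_sample, expected_umi = sample_name, umi5 + umi3
        expected_seq = insert
    else:
        expected_sample = entry.no_three_prime_match_name
        expected_umi = umi5
        expected_seq = insert[: rl - len5]

    expected_mate_seq = None
    if spec.paired:
        assert mate is not None
        # mate output: 3' prefix stripped, reverse adapter trimmed
        expected_mate_seq = mate[len3 : len3 + ((len(insert) + len5) if read_through else rl - len3)]

    # substitution errors, injected after certification
    forward = _substitute(
        forward, entry.five_prime.barcode_positions,
        spec.error_rate_five_prime_core, rng,
    )
    if pat3 is not None and read_through and not spec.paired:
        start3 = len5 + len(insert)
        forward = _substitute(
            forward, [start3 + p for p in pat3.barcode_positions],
            spec.error_rate_three_prime_core, rng,
        )
    insert_end = min(len5 + len(insert), rl)
    forward = _substitute(
        forward, range(len5, insert_end), spec.error_rate_insert, rng
    )

    qual = _HIGH_QUAL * len(forward)
    if spec.low_quality_tail:
        k = min(spec.low_quality_tail, len(qual))
        qual = qual[: len(qual) - k] + _LOW_QUAL * k

    if spec.paired:
        if pat3 is not None:
            mate = _substitute(
                mate, [len3 - 1 - p for p in pat3.barcode_positions],
                spec.error_rate_three_prime_core, rng,
            )
        rec = ((identifier, forward, qual), (identifier, mate, _HIGH_QUAL * len(mate)))
    else:
        rec = (identifier, forward, qual)
    tr = TrueRead(
        identifier=identifier,
        sample_name=expected_sample,
        umi=expected_umi,
        expected_sequence=expected_seq,
        read_through=read_through,
        expected_mate_sequence=expected_mate_seq,
    )
    return rec, tr


def write_lane(records, truth, fastq_path: str, truth_path: str | None = None,
               fastq_path_2: str | None = None) -> None:
    """Write a generated lane as gzip FASTQ (two files if paired) plus a truth TSV."""
    paired = bool(records) and isinstance(records[0][0], tuple)
    if paired and fastq_path_2 is None:
        raise ValueError("paired records require fastq_path_2")

    def _dump(recs, path):
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt") as fh:
            for rid, seq, qual in recs:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    if paired:
        _dump([r[0] for r in records], fastq_path)
        _dump([r[1] for r in records], fastq_path_2)
    else:
        _dump(records, fastq_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("identifier\tsample\tumi\texpected_sequence\tread_through\n")
            for tr in truth:
                fh.write(
                    f"{tr.identifier}\t{tr.sample_name}\t{tr.umi}\t"
                    f"{tr.expected_sequence}\t{int(tr.read_through)}\n"
                )


def random_cores(count: int, length: int, min_distance: int,
                 rng: random.Random) -> list[str]:
    """Greedily pick `count` cores with pairwise Hamming distance >= min_distance."""
    cores: list[str] = []
    attempts = 0
    while len(cores) < count:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("cannot find enough well-separated barcode cores")
        cand = _random_seq(length, rng)
        if all(sum(a != b for a, b in zip(cand, c)) >= min_distance for c in cores):
            cores.append(cand)
    return cores


def simulated_sheet(
    n_five_only: int = 6,
    n_combinatorial_entries: int = 2,
    n_three_per_entry: int = 2,
    seed: int = 0,
    five_core_length: int = 5,
    three_core_length: int = 3,
) -> SampleSheet:
    """A well-separated sheet mixing 5'-only and combinatorial entries.

    5' cores are pairwise Hamming distance >= 3 apart (unambiguous at one
    allowed mismatch); 3' cores within an entry are >= 2 apart. Patterns
    follow the common iCLIP anatomy: ``NNN<core>NN`` on the 5' side,
    ``NN<core>`` on the 3' side.
    """
    rng = random.Random(seed)
    n5 = n_five_only + n_combinatorial_entries
    cores5 = random_cores(n5, five_core_length, 3, rng)
    lines = [f"NNN{core}NN" for core in cores5[:n_five_only]]
    for core in cores5[n_five_only:]:
        cores3 = random_cores(n_three_per_entry, three_core_length, 2, rng)
        lines.append(",".join([f"NNN{core}NN"] + [f"NN{c3}" for c3 in cores3]))
    return parse_sample_sheet("\n".join(lines))
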