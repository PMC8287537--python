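"""Streaming demultiplexing: chunked FASTQ input, worker pool, ordered output.

The whole pipeline runs in a single read–write cycle: records are streamed
in fixed-size chunks, each chunk is processed (optionally by a pool of
worker processes), and results are written back strictly in input order, so
every output file is byte-identical regardless of the thread count. Output
gzip streams are written with a zeroed mtime and no filename field for the
same reason.

Outputs per run: one gzip FASTQ per sample (a _Fwd/_Rev pair in paired
mode), a no-match file (suppressible), one "no 3' match" file per
combinatorial entry for reads whose 5' barcode matched but whose 3' barcode
could not be assigned, and a tab-separated statistics summary.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import shutil
import sys
from dataclasses import dataclass, field
from multiprocessing import get_context
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcodes import SampleSheet
from .engine import (
    Category,
    DemuxIndexes,
    MalformedReadError,
    ReadRecord,
    TrimConfig,
    build_indexes,
    process_pair,
    process_read,
)
from .matching import DEFAULT_FULL_TABLE_CAP

logger = logging.getLogger("fastqplex")

DEFAULT_PREFIX = "demux"
DEFAULT_CHUNK_SIZE = 40_000
DEFAULT_COMPRESSLEVEL = 5

NO_MATCH_SAMPLE = "no_match"


@dataclass
class RunStats:
    """Per-run accounting; categories partition the input reads exactly."""

    total_reads: int = 0
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    no_match: int = 0
    too_short: int = 0
    awaiting_three_prime: dict[str, int] = field(default_factory=dict)
    malformed: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.per_sample_counts.values())

    @property
    def awaiting(self) -> int:
        return sum(self.awaiting_three_prime.values())

    @property
    def category_total(self) -> int:
        return self.assigned + self.awaiting + self.no_match + self.too_short

    def conservation_holds(self) -> bool:
        return self.category_total == self.total_reads


def output_path(
    sample_name: str,
    prefix: str,
    output_dir: str,
    mate: int | None = None,
) -> str:
    """Deterministic per-sample output path.

    ``mate`` is None for single-end, 1/2 for the forward/reverse file of a
    pair.
    """
    suffix = "" if mate is None else ("_Fwd" if mate == 1 else "_Rev")
    return os.path.join(output_dir, f"{prefix}_{sample_name}{suffix}.fastq.gz")


#: Block size fed to the gzip compressor. Deflate block boundaries depend on
#: write-call chunking, so both the direct and the ultra (compress-at-close)
#: paths feed the compressor in blocks of exactly this size to guarantee
#: byte-identical output.
_GZ_BLOCK = 65536


class _FastqWriter:
    """Gzip FASTQ writer with reproducible bytes (mtime=0, nameless header).

    In *ultra* mode records go to an uncompressed temporary first and are
    compressed once at close; final bytes match the direct path because the
    compressor sees the same byte sequence in the same block sizes.
    """

    def __init__(self, path: str, compresslevel: int, ultra: bool) -> None:
        self.path = path
        self.compresslevel = compresslevel
        self.ultra = ultra
        self.records = 0
        if ultra:
            self._tmp_path = path + ".tmp"
            self._fh = open(self._tmp_path, "wb")
        else:
            self._raw = open(path, "wb")
            self._gz = gzip.GzipFile(
                filename="", mode="wb", fileobj=self._raw,
                compresslevel=compresslevel, mtime=0,
            )
            self._buffer = bytearray()

    def write(self, identifier: str, sequence: str, quality: str) -> None:
        data = f"@{identifier}\n{sequence}\n+\n{quality}\n".encode("ascii")
        self.records += 1
        if self.ultra:
            self._fh.write(data)
            return
        self._buffer += data
        while len(self._buffer) >= _GZ_BLOCK:
            self._gz.write(bytes(self._buffer[:_GZ_BLOCK]))
            del self._buffer[:_GZ_BLOCK]

    def close(self) -> None:
        if self.ultra:
            self._fh.close()
            with open(self._tmp_path, "rb") as src, open(self.path, "wb") as raw:
                gz = gzip.GzipFile(
                    filename="", mode="wb", fileobj=raw,
                    compresslevel=self.compresslevel, mtime=0,
                )
                shutil.copyfileobj(src, gz, _GZ_BLOCK)
                gz.close()
            os.remove(self._tmp_path)
        else:
            if self._buffer:
                self._gz.write(bytes(self._buffer))
                self._buffer.clear()
            self._gz.close()
            self._raw.close()


def _open_text(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def _iter_fastq(path: str, stats: RunStats) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual); a truncated/garbled tail is warned and skipped."""
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                yield next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                logger.warning("truncated or malformed FASTQ record in %s: %s", path, exc)
                stats.malformed += 1
                return


def _chunked(iterable: Iterable, size: int) -> Iterator[list]:
    chunk: list = []
    for item in iterable:
        chunk.append(item)
        if len(chunk) >= size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


class _ChunkProcessor:
    """Picklable per-chunk worker: raw record tuples in, outcome tuples out."""

    def __init__(
        self,
        sheet: SampleSheet,
        indexes: DemuxIndexes,
        cfg: TrimConfig,
        paired: bool,
    ) -> None:
        self.sheet = sheet
        self.indexes = indexes
        self.cfg = cfg
        self.paired = paired

    def __call__(self, chunk: list) -> list:
        results = []
        for item in chunk:
            try:
                if self.paired:
                    (fid, fseq, fqual), (rid, rseq, rqual) = item
                    out = process_pair(
                        ReadRecord(fid, fseq, fqual),
                        ReadRecord(rid, rseq, rqual),
                        self.sheet, self.indexes, self.cfg,
                    )
                else:
                    fid, fseq, fqual = item
                    out = process_read(
                        ReadRecord(fid, fseq, fqual),
                        self.sheet, self.indexes, self.cfg,
                    )
            except MalformedReadError as exc:
                logger.warning("skipping malformed record: %s", exc)
                results.append(None)
                continue
            mate = out.mate_record
            results.append((
                out.category.value,
                out.sample_name,
                out.output_record.identifier,
                out.output_record.sequence,
                out.output_record.quality,
                None if mate is None else (mate.identifier, mate.sequence, mate.quality),
            ))
        return results


_WORKER_PROCESSOR: _ChunkProcessor | None = None


def _init_worker(processor: _ChunkProcessor) -> None:
    global _WORKER_PROCESSOR
    _WORKER_PROCESSOR = processor


def _process_chunk(chunk: list) -> list:
    assert _WORKER_PROCESSOR is not None
    return _WORKER_PROCESSOR(chunk)


def _normalise_inputs(input_paths) -> tuple[list[str], bool]:
    if isinstance(input_paths, (str, os.PathLike)):
        return [os.fspath(input_paths)], False
    paths = [os.fspath(p) for p in input_paths]
    if len(paths) == 1:
        return paths, False
    if len(paths) == 2:
        return paths, True
    raise ValueError("input_paths must be one FASTQ or a (forward, reverse) pair")


def run_demux(
    input_paths,
    sheet: SampleSheet,
    cfg: TrimConfig,
    output_dir: str,
    threads: int = 1,
    prefix: str = DEFAULT_PREFIX,
    ignore_no_match: bool = False,
    ultra: bool = False,
    compresslevel: int = DEFAULT_COMPRESSLEVEL,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    full_table_cap: int = DEFAULT_FULL_TABLE_CAP,
) -> RunStats:
    """Demultiplex one FASTQ (or forward/reverse pair) into per-sample files.

    Reads are processed in `chunk_size` chunks; with ``threads > 1`` chunks
    are distributed over a process pool but written back in input order, so
    outputs are byte-identical for every thread count. Returns the run's
    :class:`RunStats`, which are also written to ``<prefix>_stats.tsv``.
    """
    if threads < 1:
        raise ValueError("threads must be >= 1")
    paths, paired = _normalise_inputs(input_paths)
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    os.makedirs(output_dir, exist_ok=True)
    if not os.access(output_dir, os.W_OK):
        raise PermissionError(f"output directory {output_dir!r} is not writable")

    indexes = build_indexes(sheet, cfg.m5, cfg.m3, paired=paired, full_table_cap=full_table_cap)
    processor = _ChunkProcessor(sheet, indexes, cfg, paired)
    stats = RunStats()

    # route name -> writer (single-end) or (fwd, rev) writer pair
    routes: dict[str, object] = {}
    route_names = list(sheet.sample_names)
    route_names += [
        e.no_three_prime_match_name for e in sheet.entries if e.three_primes
    ]
    if not ignore_no_match:
        route_names.append(NO_MATCH_SAMPLE)
    all_paths: list[str] = []
    for name in route_names:
        if paired:
            p1 = output_path(name, prefix, output_dir, mate=1)
            p2 = output_path(name, prefix, output_dir, mate=2)
            all_paths += [p1, p2]
        else:
            all_paths.append(output_path(name, prefix, output_dir))
    if len(set(all_paths)) != len(all_paths):
        raise ValueError("output filename collision between samples")
    for name in route_names:
        if paired:
            routes[name] = (
                _FastqWriter(output_path(name, prefix, output_dir, 1), compresslevel, ultra),
                _FastqWriter(output_path(name, prefix, output_dir, 2), compresslevel, ultra),
            )
        else:
            routes[name] = _FastqWriter(
                output_path(name, prefix, output_dir), compresslevel, ultra
            )

    if paired:
        records: Iterable = zip(_iter_fastq(paths[0], stats), _iter_fastq(paths[1], stats))
    else:
        records = _iter_fastq(paths[0], stats)
    chunks = _chunked(records, chunk_size)

    pool = None
    try:
        if threads > 1:
            ctx = get_context("fork") if sys.platform.startswith("linux") else get_context()
            pool = ctx.Pool(threads, initializer=_init_worker, initargs=(processor,))
            result_iter: Iterator[list] = pool.imap(_process_chunk, chunks)
        else:
            result_iter = map(processor, chunks)
        for chunk_results in result_iter:
            for res in chunk_results:
                if res is None:
                    stats.malformed += 1
                    continue
                stats.total_reads += 1
                cat = Category(res[0])
                sample = res[1]
                if cat is Category.ASSIGNED:
                    stats.per_sample_counts[sample] = (
                        stats.per_sample_counts.get(sample, 0) + 1
                    )
                    _write_route(routes[sample], res, paired)
                elif cat is Category.FIVE_ONLY_AWAITING_3BC:
                    stats.awaiting_three_prime[sample] = (
                        stats.awaiting_three_prime.get(sample, 0) + 1
                    )
                    _write_route(routes[sample], res, paired)
                elif cat is Category.NO_MATCH:
                    stats.no_match += 1
                    if not ignore_no_match:
                        _write_route(routes[NO_MATCH_SAMPLE], res, paired)
                else:  # TOO_SHORT: counted, never written
                    stats.too_short += 1
    finally:
        if pool is not None:
            pool.close()
            pool.join()
        for writer in routes.values():
            if paired:
                writer[0].close()  # type: ignore[index]
                writer[1].close()  # type: ignore[index]
            else:
                writer.close()  # type: ignore[union-attr]

    _write_stats(stats, os.path.join(output_dir, f"{prefix}_stats.tsv"))
    logger.info(
        "%d reads: %d assigned, %d awaiting 3' barcode, %d no match, %d too short",
        stats.total_reads, stats.assigned, stats.awaiting,
        stats.no_match, stats.too_short,
    )
    return stats


def _write_route(writer, res, paired: bool) -> None:
    if paired:
        writer[0].write(res[2], res[3], res[4])
        mid, mseq, mqual = res[5]
        writer[1].write(mid, mseq, mqual)
    else:
        writer.write(res[2], res[3], res[4])


def _write_stats(stats: RunStats, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("category\tname\treads\n")
        for name in sorted(stats.per_sample_counts):
            fh.write(f"sample\t{name}\t{stats.per_sample_counts[name]}\n")
        for name in sorted(stats.awaiting_three_prime):
            fh.write(f"no_3bc_match\t{name}\t{stats.awaiting_three_prime[name]}\n")
        fh.write(f"no_match\t-\t{stats.no_match}\n")
        fh.write(f"too_short\t-\t{stats.too_short}\n")
        fh.write(f"malformed_skipped\t-\t{stats.malformed}\n")
        fh.write(f"total\t-\t{stats.total_reads}\n")
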