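# Methods

## Problem setting

Complex multiplexed sequencing libraries (iCLIP-style protein–RNA
crosslinking, ribosome profiling and relatives) place sample barcodes inside
the read: always at the 5' end of the forward read, optionally also at the
3' end of the insert ("combinatorial" barcoding, where the sample is the
unique 5'+3' pair). Barcode bases are interleaved with randomers (UMIs,
written `N` in patterns) used after alignment to collapse PCR duplicates.
Downstream of the insert lies the 3' sequencing adapter. `fastqplex` splits
such a lane into per-sample files, relocates UMIs into read headers, and
trims adapters and low-quality tails, in one streaming pass.

## Barcode model and compatibility

A pattern is a string over `{A,C,G,T,N}`; its defined bases (the *core*)
identify the sample, its `N` positions are UMI bases recorded per read.
5' patterns are anchored at the read start, 3' patterns at the read end.
Within a sheet, all 5' patterns must place their core bases at identical
offsets from the 5' end; within one entry, all linked 3' patterns must place
theirs at identical offsets from the 3' end. That is the entire
compatibility rule: UMI stretches — and hence total pattern lengths — may
differ between patterns, and 3' families belonging to different 5' barcodes
are fully independent of each other. Sheets violating these rules are
rejected at parse time with the offending lines named. Unnamed samples get
deterministic names (`5bc_<core>`, `5bc_<5core>_3bc_<3core>`); duplicate
cores or duplicate sample names are hard errors because output files would
collide.

## Assignment by precomputed best match

The matching metric is positional (Hamming) distance evaluated at core
offsets only. An `N` in the *read* at a core offset counts as one mismatch
against every defined base — the conservative reading that still lets
N-containing reads be rescued within the mismatch budget. Characters
outside the alphabet at a core offset yield no match; at UMI offsets they
are irrelevant.

For a family with last core offset at position `L-1`, the table is built
over all `5^L` windows (alphabet `ACGTN`): each window is scored against
every pattern; the outcome is *unique* if exactly one pattern attains the
minimal distance within the budget, *ambiguous* (read discarded) on a tie,
*none* otherwise. Per read, assignment is then one dictionary lookup of the
read's prefix (5') or end-anchored suffix (3'). The key window runs through
the last core base rather than the full pattern length, because compatible
patterns may have different total lengths; after a unique match, slicing
and UMI extraction use the matched pattern's own length and mask, which is
outcome-equivalent to keying on full-length windows.

Full enumeration is capped at `5^7` keys (78,125; built in well under a
second); longer windows switch to a memoized on-demand table with identical
semantics — the equivalence is covered by a dedicated test. Raising the
mismatch budget can only add matches, never demote a unique one; permuting
pattern order only relabels indices. Both properties are tested.

## Read pipeline

Order of operations per forward read: 5' detection → adapter trim →
quality trim → 3' detection → minimum-length filter.

- **Adapter trimming** is a semi-global, mismatch-only scan (no indels):
  the leftmost start position where the adapter — or an adapter prefix
  overhanging the read's 3' end — matches with error fraction ≤ 0.1 over an
  overlap of ≥ 3 bases wins, and the read is cut there. Defaults follow the
  convention of the established trimmer family (Illumina universal adapter
  `AGATCGGAAGAGC`, 10% error rate); keeping the model indel-free keeps the
  simulator's truth exact.
- **Quality trimming** uses the BWA-style running-sum rule: scanning from
  the 3' end, accumulate `q_threshold − phred(base)` and cut at the
  maximum of the running sum, stopping once it drops below zero.
  Threshold 0 disables trimming. Phred encoding is fixed at +33.
- **3' barcode detection (single-end)** is gated on adapter evidence: a 3'
  barcode may only be assigned when at least `min_overlap_for_3bc`
  (default 3, inclusive) adapter bases were trimmed, certifying that the
  read's end is the insert's true end. Reads passing the 5' match but
  failing 3' assignment go to a per-entry `*_no3bc` file rather than the
  global no-match pool, so they remain recoverable. Quality trimming runs
  *before* the 3' window is sliced; the alternative order differs only for
  low-quality barcode bases.
- **Paired mode** reads the 3' barcode from the start of the reverse read
  in reverse-complement orientation (the physical geometry of read-through
  sequencing), with no adapter gate; the captured UMI is flipped back to
  forward-strand orientation before header insertion. When the mate assigns
  a 3' barcode and the forward read's adapter was detected with the same
  ≥ 3-base evidence, the matched 3' pattern length is also stripped from
  the forward read's end, so output sequences never retain barcode or UMI
  bases. The minimum-length filter is evaluated on the forward read.
- **UMI header format**: `identifier` + `_rbc:` + 5' UMI (+ 3' UMI when
  assigned), inserted before the first whitespace — compatible with
  deduplicators that split on the last underscore.

Every read lands in exactly one category (assigned / awaiting 3' barcode /
no match / too short); the category counts must sum to the input count, and
this conservation is asserted across the test lanes.

## Streaming, parallelism, determinism

Records are read in chunks of 40,000 (the work-unit default), processed
inline or by a process pool, and written strictly in input order, making
per-sample outputs byte-identical for any thread count. Gzip members are
written with zeroed mtime and no filename field, and the compressor is fed
in fixed 64 KiB blocks in both the direct and the "ultra" path
(uncompressed temporaries compressed at close), because deflate block
boundaries depend on write chunking; this makes byte-level determinism
testable rather than merely likely. Compression level defaults to 5.
SLURM-based remote compression is accepted as a flag for command-line
compatibility but warned as unsupported — cluster-scheduler integration is
environment-specific and out of scope.

## Synthetic lanes and what they show

The simulator assembles molecules with the library anatomy above
(5' UMI+barcode, insert, optional 3' barcode+UMI) and derives the forward
read (molecule + adapter + random filler, truncated to the read length,
default 100 nt) and, in paired mode, the mate (reverse complement of the
molecule + reverse adapter). Default conditions: 25–45 nt inserts (typical
for the short cDNA fragments of these protocols), constant Phred-40
qualities with an optional low-quality tail, substitution errors at
configurable per-region rates, and a configurable fraction of
non-read-through molecules whose insert extends past the read end.

Two deliberate cleanliness guarantees make zero-error truth exact rather
than overwhelmingly likely: inserts and fillers are rejection-sampled until
the adapter occurs at exactly the intended position and nowhere earlier
under the pipeline's own scan, and non-read-through reads are certified
adapter-free. Without this, chance 3-mer suffix matches (~2% of random
reads) would trip the adapter gate for reasons unrelated to the logic under
test. Errors, when requested, are injected after certification.

The simulator emulates substitutions only — no indels, no per-cycle error
profiles, no quality-dependent error rates, no optical duplicates. Tests
passing on these lanes therefore demonstrate the correctness of barcode
arithmetic, trimming bookkeeping and routing, not robustness to error modes
outside the substitution model. With substitution rate `r` on a length-`k`
core and budget 0, assignment accuracy is predicted by `(1−r)^k`; the test
suite checks this against binomial sampling error.

## Defaults and problem sizes

CLI defaults: `-m5 1 -m3 0 -q 20 -t 4 -l 20`, adapter `AGATCGGAAGAGC` on
both mates, `-mt 3`. The test suite and the acceptance script use lanes of
2,000–50,000 reads with 4–10 samples — large enough for the binomial checks
and byte-level determinism sweeps to be meaningful, small enough to run as
an ordinary desktop test suite. The oracle-equivalence sweep covers 50
randomized families (window length ≤ 6, ≤ 6 patterns, budgets ≤ 2),
exhausting all `5^L` candidates per family.

## Known limitations

- Barcodes must sit at fixed positions relative to a read end; barcodes at
  unknown internal positions need different algorithms and are out of scope.
- No indel-tolerant barcode or adapter matching.
- No probabilistic, quality-weighted assignment; no demultiplexing by
  Illumina index reads (the instrument's job).
- Single-end combinatorial assignment inherently misses samples whose
  inserts exceed read length minus barcode and adapter-evidence lengths;
  such reads are preserved in the per-entry `*_no3bc` files.
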