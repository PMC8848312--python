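# Methods

## The compression model

`mbgcpy` is a referential LZ codec for ordered collections of FASTA
genomes. Its premise is that same-species genomes differ by point
mutations, short indels and segmental inversions, so nearly all of each
new genome already exists — forward or reverse-complemented — in the
genomes seen before it. The codec therefore maintains one mutable
dictionary, the reference string REF, and expresses every contig as a
factorization into

- **match tokens** `(offset, length)`: `length` symbols copied from REF at
  `offset` (0-based, half-open intervals throughout), and
- **literal runs**: symbols emitted verbatim.

Because every append to REF places a contig *and* its reverse complement,
an RC-match is an ordinary match into the RC half — tokens carry no
orientation bit and the decoder needs no RC logic at all.

Two modes exist. In the **default mode** REF is initialised with the first
genome G₁ followed by rc(G₁); G₁ itself travels to the decoder through the
literal stream. In the **max mode** REF starts empty and G₁ is processed
like any other genome: its first contig is (vacuously) all-literal,
trips the append rule, and seeds REF that way. Max mode also allows a much
larger REF and a stronger back-end preset, trading speed for ratio.

## Matching

Seeds are k-mers (default k = 32) sampled from REF with a stride of 16
symbols into a fixed-size hash table of 2²⁵ slots holding one REF position
each; a colliding insert overwrites the previous occupant, and a lookup is
a single probe — constant time by construction. Seeds containing non-ACGT
symbols are never indexed and never looked up. The hash packs the k-mer
2 bits/symbol into a 64-bit word and applies a splitmix64 finalizer; for
k > 32 the leading symbols fall off the word, which only adds collisions
that verification filters anyway.

Encoding a contig scans left to right. Every position whose k-mer hits an
occupied slot is a candidate; the stored REF position is verified by direct
k-symbol comparison (this also neutralises stale entries left behind by
circular overwrites) and then extended maximally: right, up to the contig
end and the REF valid extent; left, while symbols match, consuming pending
literal symbols and **swallowing** wholly covered previously emitted
tokens. A partially overlapped earlier token truncates the left extension
at its end rather than being split — matches stay intact, factorizations
stay exact. A match shorter than k after truncation is discarded. After
emitting a match over `[s, e)` the scan resumes at `max(e − m, s + 1)`
with skip margin m = 16; the `s + 1` floor is what guarantees termination.
Matches never cross contig boundaries on the target side; on the REF side
the buffer is a flat concatenation and matches may span whatever is
adjacent in it — the decoder replays the same flat buffer, so this is
self-consistent.

With swallowing disabled (a test/benchmark toggle) no left extension is
performed at all: the match starts at the seed position. This is also the
configuration under which the engine is compared against the brute-force
greedy LZ oracle in the tests.

## The append policy and the circular buffer

After a contig is factored, it is appended to REF (with its reverse
complement) iff its literal symbols strictly exceed 1/u of its length
(u = 192): `unmatched · u > len`. Contigs almost fully covered by matches
are nearly redundant and would only inflate the dictionary. REF is capped
(2³² bytes default, 2⁴⁰ max mode; configurable); once full it becomes a
circular buffer overwritten from position 0. Index entries pointing into
overwritten regions are not purged — verification against current REF
content rejects or re-purposes them, and since the decoder replays the
same buffer, even a match that "accidentally" verifies against newer
content decodes correctly. The decoder reads the append decision from a
per-contig flag stream instead of recomputing the 1/u rule, decoupling it
from encoder heuristics.

## Streams and back-end

An encoded collection separates into ten streams (FORMAT.md): file names,
per-file contig counts, headers, per-contig token counts, token kinds,
match offsets, match lengths, literal-run lengths, literal bytes, and
appended flags. Integers are LEB128 varints, flags bit-packed, text
NUL-separated; offsets are stored absolute. Each stream is compressed
independently with LZMA (preset 6 in default mode, 9 in max mode) behind a
per-stream backend-id byte that keeps the container extensible. The
default/max distinction is purely a preset level; there is no block
splitting, so output is bit-deterministic for fixed input and parameters.
Encoding is strictly single-worker and order-preserving by design — the
determinism contract takes precedence over throughput, and the CLI's
`--threads` flag is accepted only for interface familiarity.

## Parameters

| name | default | meaning |
|------|---------|---------|
| k | 32 | seed length (symbols); ≥ 4, smaller values for tiny test inputs |
| stride | 16 | REF index sampling interval |
| m | 16 | skip margin after a match |
| u | 192 | append divisor of the unmatched-fraction rule |
| table_bits | 25 | log₂ hash slots (the table is a flat int64 array) |
| ref_limit | 2³² / 2⁴⁰ | REF capacity, default / max mode |
| rc_enabled | on | append reverse complements to REF |
| swallow | on | left-extension swallowing |
| backend_level | 6 / 9 | LZMA preset, default / max mode |

k and the hash are free design choices here: k = 32 keeps random 32-mer
collisions negligible at bacterial scale while one 64-bit word still holds
the packed seed. Lowercase input is uppercased on read; soft-masking is
not preserved. End-of-line bytes inside sequences are normalisation noise:
removed on read, re-inserted at a user-chosen width on write.

## The synthetic-data generator

Tests and the acceptance script run on generated collections: a uniform
i.i.d. ancestor; per-genome SNPs (substitution to a different base at a
per-symbol rate), indels (per-symbol rate, geometric lengths, mean 3),
inversions (Poisson count per genome, uniform length in a range, segment
replaced by its reverse complement) and fragmentation into contigs at
uniform cut points. Each genome uses an independent PCG64 substream keyed
by `(seed, genome_index)`, so collections are extensible without
perturbing existing members and are byte-reproducible. The standard
fixture suite holds three 8-genome, 50 kb-ancestor collections: SNP-only,
mixed, and inversion-rich (the latter carries most of its divergence as
RC inversions and is the designated RC-matching stressor).

What the generator does *not* emulate: repeat families, mobile elements,
horizontal transfer, GC skew, rearrangements other than inversion, or
real assembly artefacts. Passing tests therefore demonstrate the codec's
correctness contracts (losslessness, determinism, buffer discipline) and
the direction and rough magnitude of its design effects (RC matching,
swallowing, redundancy scaling) — not ratios attainable on any particular
real dataset.

## Problem sizes and numerical choices

Desk-scale sizes keep the whole suite in tens of seconds: the randomized
round-trip sweep uses 200 collections of 2–4 genomes over 0.8–5 kb
ancestors across both modes, RC on/off, k ∈ {4, 8, 32}, stride ∈ {1, 16},
m ∈ {0, 16} and wrap-forcing REF limits; the redundancy-scaling experiment
uses 1/10/100 near-identical 1-Mb genomes at defaults; the circular-buffer
stress encodes ~10 MB against a 64 kB REF. The oracle comparison runs the
engine at stride 1, m 0, swallowing off on ≤ 200 bp pairs whose reference
k-mers are collision-free at the chosen table size (pairs violating that
precondition are re-drawn deterministically), since a hash collision makes
the single-occupant table legitimately blind to one of the colliding
k-mers.

Degenerate inputs are first-class: empty collections, empty files, empty
contigs, contigs shorter than k, and N runs (N never seeds, and extends
only across N in REF, since extension compares raw bytes) all round-trip.

## Known limitations

- No random access: extracting one genome replays the archive prefix.
- The container is not compatible with the original MBGC format, and PPMd
  is not offered as a back-end (all streams use LZMA).
- Throughput is far below a tuned native implementation's; the engine
  vectorises hashing and candidate gathering but remains Python at heart.
- A single hash-table occupant per slot means a repeated k-mer is only
  findable at its most recently indexed position; coverage can in corner
  cases fall below what an exhaustive matcher would achieve.
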