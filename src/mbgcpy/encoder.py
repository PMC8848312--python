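"""Referential LZ encoder with a reverse-complement-aware reference buffer.

The encoder factors every contig of a genome collection into LZ-matches
``(ref_offset, length)`` against a single growing reference string REF and
literal runs for whatever stays uncovered.  REF starts (in the default mode)
as the first genome followed by its reverse complement, so matches against
reverse-complemented content need no orientation flag: RC copies physically
live in REF.  A contig whose unmatched fraction exceeds ``1/u`` of its
length is appended to REF (again with its reverse complement); once REF hits
its capacity it turns into a circular buffer and new content overwrites it
from the start.

Match discovery is seed-and-extend: a fixed-size hash table indexes k-mer
seeds sampled from REF with a stride, a table hit is verified against REF
and extended maximally in both directions, and the left extension may
"swallow" wholly covered earlier tokens.  After a match, scanning resumes a
skip margin ``m`` before the match end, which lets longer overlapping
matches be found.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .fasta import Contig, GenomeFile
from .seqs import CODE_LUT, hash_positions, reverse_complement

__all__ = [
    "EncoderParams", "ReferenceState", "MatchToken", "LiteralRun",
    "ContigEncoding", "StreamSet", "ConfigError",
    "init_reference", "init_reference_empty", "encode_contig",
    "unmatched_exceeds_threshold", "encode_collection",
]

DEFAULT_REF_LIMIT = 2 ** 32       # default mode cap on REF
MAX_MODE_REF_LIMIT = 2 ** 40      # max mode cap on REF


class ConfigError(ValueError):
    """Invalid encoder configuration (e.g., first genome exceeds REF limit)."""


@dataclass(frozen=True)
class EncoderParams:
    """Tunable knobs of the match engine.

    k            seed length in symbols (>= 4)
    stride       REF index sampling interval (default 16)
    m            skip margin: scan resumes m symbols before a match end
    u            append divisor: append a contig to REF iff unmatched*u > len
    table_bits   log2 of hash-table slots (default 25)
    ref_limit    REF capacity in bytes; None picks the mode default
                 (2**32 default mode, 2**40 max mode)
    rc_enabled   also place reverse complements in REF
    mode         "default" (REF seeded with G1 + rc(G1)) or "max" (empty REF)
    swallow      left-extend matches, absorbing wholly covered prior tokens
    backend_level  LZMA preset; None picks 6 (default mode) / 9 (max mode)
    debug        verify each factorization inline against the contig
    """

    k: int = 32
    stride: int = 16
    m: int = 16
    u: int = 192
    table_bits: int = 25
    ref_limit: Optional[int] = None
    rc_enabled: bool = True
    mode: str = "default"
    swallow: bool = True
    backend_level: Optional[int] = None
    debug: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("default", "max"):
            raise ConfigError(f"unknown mode: {self.mode!r}")
        if self.k < 4:
            raise ConfigError("k must be >= 4")
        if self.stride < 1 or self.m < 0 or self.u < 1:
            raise ConfigError("stride >= 1, m >= 0, u >= 1 required")
        if not (8 <= self.table_bits <= 40):
            raise ConfigError("table_bits must be in [8, 40]")
        if self.ref_limit is not None and self.ref_limit < 1:
            raise ConfigError("ref_limit must be positive")

    @property
    def effective_ref_limit(self) -> int:
        if self.ref_limit is not None:
            return self.ref_limit
        return MAX_MODE_REF_LIMIT if self.mode == "max" else DEFAULT_REF_LIMIT

    @property
    def effective_backend_level(self) -> int:
        if self.backend_level is not None:
            return self.backend_level
        return 9 if self.mode == "max" else 6

    def normalized(self) -> "EncoderParams":
        """Codec-relevant view with mode defaults materialised (what an
        archive echoes back; ``debug`` is not a codec parameter)."""
        return replace(self, ref_limit=self.effective_ref_limit,
                       backend_level=self.effective_backend_level,
                       debug=False)


@dataclass(frozen=True)
class MatchToken:
    ref_offset: int
    length: int


@dataclass(frozen=True)
class LiteralRun:
    data: bytes

    @property
    def length(self) -> int:
        return len(self.data)


@dataclass
class ContigEncoding:
    tokens: list            # ordered MatchToken | LiteralRun
    unmatched: int          # total literal symbols
    appended: bool = False  # did this contig extend REF?


class ReferenceState:
    """REF byte buffer with append cursor, circular overwrite and seed index.

    The decoder replays the same buffer without the index
    (``with_index=False``): correctness never depends on the hash table.
    """

    def __init__(self, params: EncoderParams, with_index: bool = True):
        self.params = params
        self.ref = bytearray()
        self.limit = params.effective_ref_limit
        self.wrapped = False
        self.write_pos = 0
        self.table: Optional[np.ndarray] = (
            np.full(1 << params.table_bits, -1, dtype=np.int64)
            if with_index else None
        )

    @property
    def extent(self) -> int:
        """Valid REF length; equals ``limit`` forever once wrapped."""
        return len(self.ref)

    # kept as a distinct name to mirror the append-cursor notion
    @property
    def end(self) -> int:
        return self.limit if self.wrapped else len(self.ref)

    def index_range(self, lo: int, hi: int) -> None:
        """Index seeds at ``lo, lo+stride, ...`` with ``p + k <= hi``.

        Invalid seeds (non-ACGT) are skipped; a hash collision overwrites
        the previous occupant, so the table always holds the latest
        position per slot.
        """
        if self.table is None:
            return
        k, stride = self.params.k, self.params.stride
        if hi - lo < k:
            return
        pos = np.arange(lo, hi - k + 1, stride, dtype=np.int64)
        codes = CODE_LUT[np.frombuffer(memoryview(self.ref)[lo:hi],
                                       dtype=np.uint8)]
        slots, valid = hash_positions(codes, pos - lo, k,
                                      self.params.table_bits)
        # in-order scatter: for duplicate slots the later position wins
        self.table[slots[valid]] = pos[valid]

    def append_raw(self, data: bytes) -> None:
        """Append bytes, overwriting circularly past the capacity limit."""
        view = memoryview(data)
        if not self.wrapped:
            take = min(self.limit - len(self.ref), len(view))
            if take:
                old = len(self.ref)
                self.ref += view[:take]
                self.index_range(old, len(self.ref))
                view = view[take:]
            if not len(view):
                return
            self.wrapped = True
            self.write_pos = 0
        while len(view):
            w = min(self.limit - self.write_pos, len(view))
            self.ref[self.write_pos:self.write_pos + w] = view[:w]
            self.index_range(self.write_pos, self.write_pos + w)
            self.write_pos += w
            if self.write_pos == self.limit:
                self.write_pos = 0
            view = view[w:]

    def append_contig(self, seq: bytes) -> None:
        """Append a contig (and, when RC is enabled, its reverse complement)."""
        if not seq:
            return
        chunk = seq + reverse_complement(seq) if self.params.rc_enabled else seq
        self.append_raw(chunk)


def init_reference(first_genome: GenomeFile, params: EncoderParams,
                   with_index: bool = True) -> ReferenceState:
    """Default-mode REF: the first genome followed by its reverse complement.

    Contigs are concatenated before the RC copy is taken.  A first genome
    whose (doubled) size exceeds the REF capacity is a configuration error.
    """
    state = ReferenceState(params, with_index=with_index)
    concat = b"".join(c.seq for c in first_genome.contigs)
    need = 2 * len(concat) if params.rc_enabled else len(concat)
    if need > state.limit:
        raise ConfigError(
            f"first genome ({len(concat)} bytes) does not fit the REF limit "
            f"({state.limit} bytes)")
    state.append_contig(concat)
    return state


def init_reference_empty(params: EncoderParams,
                         with_index: bool = True) -> ReferenceState:
    """Max-mode REF: empty; the first genome is matched (vacuously all
    literal) and appended through the standard unmatched-fraction policy."""
    return ReferenceState(params, with_index=with_index)


def _common_prefix_len(a, ai: int, a_end: int, b, bi: int, b_end: int) -> int:
    """Length of the common run of a[ai:a_end) and b[bi:b_end), chunked."""
    n = min(a_end - ai, b_end - bi)
    got, chunk = 0, 256
    while got < n:
        step = min(chunk, n - got)
        ca = bytes(a[ai + got:ai + got + step])
        cb = bytes(b[bi + got:bi + got + step])
        if ca == cb:
            got += step
            chunk = min(chunk * 4, 1 << 20)
        else:
            diff = np.frombuffer(ca, np.uint8) != np.frombuffer(cb, np.uint8)
            return got + int(np.argmax(diff))
    return n


def _common_suffix_len(a, ai: int, b, bi: int, max_len: int) -> int:
    """Length of the common run of a[..ai) and b[..bi) read backwards."""
    got, chunk = 0, 256
    while got < max_len:
        step = min(chunk, max_len - got)
        ca = bytes(a[ai - got - step:ai - got])
        cb = bytes(b[bi - got - step:bi - got])
        if ca == cb:
            got += step
            chunk = min(chunk * 4, 1 << 20)
        else:
            diff = np.frombuffer(ca, np.uint8) != np.frombuffer(cb, np.uint8)
            # last True position, counted from the right edge
            return got + (len(ca) - 1 - int(np.nonzero(diff)[0][-1]))
    return max_len


_LIT, _MATCH = 0, 1


@dataclass
class _Tok:
    kind: int
    start: int
    end: int
    ref_off: int = -1


def _candidates(seq: bytes, state: ReferenceState):
    """All contig positions whose seed hits an occupied table slot."""
    k = state.params.k
    if state.table is None or len(seq) < k:
        return (np.empty(0, np.int64),) * 2
    codes = CODE_LUT[np.frombuffer(seq, dtype=np.uint8)]
    pos = np.arange(0, len(seq) - k + 1, dtype=np.int64)
    slots, valid = hash_positions(codes, pos, k, state.params.table_bits)
    ref_pos = state.table[slots]
    ok = valid & (ref_pos >= 0)
    return pos[ok], ref_pos[ok]


def encode_contig(contig_seq: bytes, state: ReferenceState,
                  params: EncoderParams) -> ContigEncoding:
    """Factor one contig into matches and literal runs against current REF.

    Scanning starts at position 0 and advances by 1 on a miss; a verified
    seed is extended maximally right (bounded by the contig end and the REF
    valid extent) and, when swallowing is on, left — consuming pending
    literal symbols, removing wholly covered earlier tokens and truncating
    at a partially overlapped one.  After a match at ``[s, e)`` the scan
    resumes at ``max(e - m, s + 1)``, which guarantees progress.
    """
    L = len(contig_seq)
    if L == 0:
        return ContigEncoding([], 0)
    k, m = params.k, params.m
    ref = state.ref
    extent = len(ref)
    cand_pos, cand_ref = _candidates(contig_seq, state)

    tokens: list[_Tok] = []
    pos = 0
    while True:
        ci = int(np.searchsorted(cand_pos, pos))
        if ci >= len(cand_pos):
            break
        p = int(cand_pos[ci])
        r = int(cand_ref[ci])
        pos = p + 1                       # advance past this seed on failure
        if bytes(ref[r:r + k]) != contig_seq[p:p + k]:
            continue                      # stale or colliding entry
        ext_r = _common_prefix_len(ref, r + k, extent,
                                   contig_seq, p + k, L)
        mend = p + k + ext_r
        cov = tokens[-1].end if tokens else 0
        if mend <= cov:
            continue                      # adds no new coverage
        if params.swallow:
            s = p - _common_suffix_len(ref, r, contig_seq, p, min(p, r))
            while tokens and s < tokens[-1].end:
                if s <= tokens[-1].start:
                    tokens.pop()          # swallow a wholly covered token
                else:
                    s = tokens[-1].end    # partial overlap: truncate
                    break
        else:
            s = max(p, cov)
        if mend - s < k:
            continue
        base = tokens[-1].end if tokens else 0
        if s > base:
            tokens.append(_Tok(_LIT, base, s))
        tokens.append(_Tok(_MATCH, s, mend, r - (p - s)))
        pos = max(mend - m, s + 1)
    tail = tokens[-1].end if tokens else 0
    if tail < L:
        tokens.append(_Tok(_LIT, tail, L))

    out: list = []
    unmatched = 0
    for t in tokens:
        if t.kind == _MATCH:
            out.append(MatchToken(t.ref_off, t.end - t.start))
        else:
            run = contig_seq[t.start:t.end]
            unmatched += len(run)
            out.append(LiteralRun(run))
    enc = ContigEncoding(out, unmatched)
    if params.debug:
        _check_factorization(enc, contig_seq, ref)
    return enc


def _check_factorization(enc: ContigEncoding, contig_seq: bytes,
                         ref) -> None:
    parts = []
    for t in enc.tokens:
        if isinstance(t, MatchToken):
            assert 0 <= t.ref_offset and t.ref_offset + t.length <= len(ref)
            parts.append(bytes(ref[t.ref_offset:t.ref_offset + t.length]))
        else:
            parts.append(t.data)
    assert b"".join(parts) == contig_seq, "factorization does not reproduce contig"


def unmatched_exceeds_threshold(enc: ContigEncoding, contig_len: int,
                                params: EncoderParams) -> bool:
    """Append policy: the unmatched portion must *exceed* 1/u of the length."""
    return enc.unmatched * params.u > contig_len


@dataclass
class StreamSet:
    """The separated byte streams an encoded collection boils down to."""

    filenames: list[str] = field(default_factory=list)
    contig_counts: list[int] = field(default_factory=list)   # per file
    headers: list[bytes] = field(default_factory=list)       # per contig
    token_counts: list[int] = field(default_factory=list)    # per contig
    token_kinds: list[int] = field(default_factory=list)     # 1=match, 0=literal
    offsets: list[int] = field(default_factory=list)         # per match
    lengths: list[int] = field(default_factory=list)         # per match
    literal_lens: list[int] = field(default_factory=list)    # per literal run
    literal_bytes: bytearray = field(default_factory=bytearray)
    appended_flags: list[bool] = field(default_factory=list)  # per contig
    params: EncoderParams = field(default_factory=EncoderParams)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StreamSet):
            return NotImplemented
        return (self.filenames == other.filenames
                and self.contig_counts == other.contig_counts
                and self.headers == other.headers
                and self.token_counts == other.token_counts
                and self.token_kinds == other.token_kinds
                and self.offsets == other.offsets
                and self.lengths == other.lengths
                and self.literal_lens == other.literal_lens
                and bytes(self.literal_bytes) == bytes(other.literal_bytes)
                and self.appended_flags == other.appended_flags
                and self.params.normalized() == other.params.normalized())

    def add_encoding(self, header: bytes, enc: ContigEncoding) -> None:
        self.headers.append(header)
        self.token_counts.append(len(enc.tokens))
        self.appended_flags.append(enc.appended)
        for t in enc.tokens:
            if isinstance(t, MatchToken):
                self.token_kinds.append(1)
                self.offsets.append(t.ref_offset)
                self.lengths.append(t.length)
            else:
                self.token_kinds.append(0)
                self.literal_lens.append(t.length)
                self.literal_bytes += t.data


def encode_collection(genomes: Sequence[GenomeFile], params: EncoderParams,
                      on_contig: Optional[Callable] = None) -> StreamSet:
    """Encode an ordered genome collection into a :class:`StreamSet`.

    Default mode: the first genome seeds REF and is emitted through the
    literal stream (one run per contig); the rest are matched.  Max mode:
    every genome, including the first, is matched starting from an empty
    REF.  Deterministic for fixed input and parameters.  *on_contig*, when
    given, is called as ``on_contig(file_idx, contig_idx, state)`` after
    each contig is processed (used by lockstep tests).
    """
    s = StreamSet(params=params)
    if not genomes:
        return s

    if params.mode == "default":
        state = init_reference(genomes[0], params)
    else:
        state = init_reference_empty(params)

    for fi, g in enumerate(genomes):
        s.filenames.append(g.name)
        s.contig_counts.append(len(g.contigs))
        seed_literals = params.mode == "default" and fi == 0
        for ci, contig in enumerate(g.contigs):
            if seed_literals:
                # G1 travels through the literal stream; REF got it at init
                tokens = [LiteralRun(contig.seq)] if contig.seq else []
                enc = ContigEncoding(tokens, len(contig.seq), appended=False)
            else:
                enc = encode_contig(contig.seq, state, params)
                if unmatched_exceeds_threshold(enc, len(contig.seq), params):
                    enc.appended = True
                    state.append_contig(contig.seq)
            s.add_encoding(contig.header, enc)
            if on_contig is not None:
                on_contig(fi, ci, state)
    return s
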