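"""Match engine: REF initialisation, indexing, matching, append policy."""

import numpy as np
import pytest

from mbgcpy import (Contig, ContigEncoding, EncoderParams, GenomeFile,
                    LiteralRun, MatchToken, ConfigError, encode_collection,
                    encode_contig, init_reference, init_reference_empty,
                    reverse_complement, unmatched_exceeds_threshold)
from mbgcpy.encoder import ReferenceState
from mbgcpy.seqs import hash_kmer

from conftest import make_collection, random_seq
from mbgcpy import SimParams


def _params(**kw):
    kw.setdefault("k", 4)
    kw.setdefault("table_bits", 16)
    return EncoderParams(**kw)


# ---------------------------------------------------------------- REF init

@pytest.mark.parametrize("contigs,expected_ref", [
    ([b"ACGT"], b"ACGTACGT"),            # ACGT is its own RC
    ([b"AAC"], b"AACGTT"),
    ([b"AC", b"GT"], b"ACGTACGT"),       # contigs concatenated before RC
])
def test_init_reference_content(contigs, expected_ref):
    g = GenomeFile("g", [Contig(b"c%d" % i, s) for i, s in enumerate(contigs)])
    state = init_reference(g, _params())
    assert bytes(state.ref) == expected_ref


def test_init_reference_respects_limit():
    g = GenomeFile("g", [Contig(b"c", b"ACGTACGTACGT")])
    with pytest.raises(ConfigError):
        init_reference(g, _params(ref_limit=16))


def test_init_reference_empty_for_max_mode():
    state = init_reference_empty(_params(mode="max"))
    assert state.extent == 0 and not state.wrapped


# ---------------------------------------------------------------- indexing

def test_index_stride_exceeding_range_samples_once():
    state = ReferenceState(_params(stride=16))
    state.append_raw(b"AAAAAAAA")
    assert int((state.table >= 0).sum()) == 1
    assert state.table[hash_kmer(b"AAAA", 16)] == 0


def test_index_skips_seeds_containing_n():
    state = ReferenceState(_params(stride=4))
    state.append_raw(b"ACGTNNNNACGT")
    stored = sorted(int(p) for p in state.table[state.table >= 0])
    assert stored == [8]  # position 0 overwritten by identical seed at 8; 4 invalid


def _find_collision(k=4, bits=8):
    seen = {}
    from itertools import product
    for tup in product(b"ACGT", repeat=k):
        kmer = bytes(tup)
        h = hash_kmer(kmer, bits)
        if h in seen and seen[h] != kmer:
            return seen[h], kmer, h
        seen[h] = kmer
    raise AssertionError("no collision found")


def test_collision_keeps_later_position_and_fails_verification():
    a, b, slot = _find_collision()
    params = _params(table_bits=8, stride=1, rc_enabled=False)
    state = ReferenceState(params)
    state.append_raw(a)          # indexes a at position 0
    state.append_raw(b)          # b's seed lands in the same slot
    assert int(state.table[slot]) == 4
    # a's k-mer now resolves to b's position; verification must reject it
    enc = encode_contig(a, state, params)
    assert enc.tokens == [LiteralRun(a)]
    assert enc.unmatched == len(a)


# ---------------------------------------------------------------- matching

def _replay(enc, state):
    parts = []
    for t in enc.tokens:
        if isinstance(t, MatchToken):
            parts.append(bytes(state.ref[t.ref_offset:t.ref_offset + t.length]))
        else:
            parts.append(t.data)
    return b"".join(parts)


def test_no_shared_kmers_gives_single_literal_run():
    params = _params(rc_enabled=False, stride=1)
    state = ReferenceState(params)
    state.append_raw(b"A" * 50)
    enc = encode_contig(b"C" * 30, state, params)
    assert enc.tokens == [LiteralRun(b"C" * 30)]


def test_identical_region_gives_single_match(small_params):
    rng = np.random.default_rng(3)
    ref = random_seq(rng, 500)
    # k=16: every 16-mer of a 500 bp random sequence is unique, so the
    # index resolves the true origin and one spanning match results
    params = EncoderParams(k=16, stride=1, table_bits=16, rc_enabled=False)
    state = ReferenceState(params)
    state.append_raw(ref)
    enc = encode_contig(ref[100:300], state, params)
    assert enc.tokens == [MatchToken(100, 200)]
    assert enc.unmatched == 0


def test_empty_contig_encodes_to_nothing():
    params = _params()
    state = ReferenceState(params)
    enc = encode_contig(b"", state, params)
    assert enc.tokens == [] and enc.unmatched == 0


def test_swallowing_absorbs_earlier_tokens():
    # seed found mid-contig must left-extend over pending literals and
    # wholly covered earlier matches, leaving one spanning match
    params = _params(stride=1, m=0)
    state = ReferenceState(params)
    state.append_raw(b"A" * 64)
    enc = encode_contig(b"A" * 40, state, params)
    assert len([t for t in enc.tokens if isinstance(t, MatchToken)]) == 1
    assert enc.unmatched == 0
    assert _replay(enc, state) == b"A" * 40


def test_match_never_crosses_contig_end():
    rng = np.random.default_rng(5)
    ref = random_seq(rng, 300)
    params = _params(stride=1, rc_enabled=False)
    state = ReferenceState(params)
    state.append_raw(ref)
    contig = ref[:50]
    enc = encode_contig(contig, state, params)
    assert sum(t.length if isinstance(t, MatchToken) else len(t.data)
               for t in enc.tokens) == len(contig)
    assert _replay(enc, state) == contig


def test_factorisation_reconstructs_for_divergent_contig():
    rng = np.random.default_rng(8)
    ref = random_seq(rng, 2000)
    arr = bytearray(ref)
    for i in rng.integers(0, len(arr), 40):
        arr[i] = random_seq(rng, 1)[0]
    contig = bytes(arr)
    params = EncoderParams(k=8, stride=2, table_bits=16, debug=True)
    state = ReferenceState(params)
    state.append_raw(ref)
    enc = encode_contig(contig, state, params)  # debug asserts factorization
    assert _replay(enc, state) == contig
    assert any(isinstance(t, MatchToken) for t in enc.tokens)


# ------------------------------------------------------------ append rule

@pytest.mark.parametrize("unmatched,length,expected", [
    (1, 192, False),    # 1*192 == 192, not strictly greater
    (2, 192, True),
    (0, 10 ** 9, False),
    (1, 191, True),
])
def test_unmatched_threshold_is_strict(unmatched, length, expected):
    enc = ContigEncoding([], unmatched)
    assert unmatched_exceeds_threshold(enc, length, EncoderParams()) is expected


def test_append_writes_contig_and_rc():
    state = ReferenceState(_params())
    state.append_contig(b"AAC")
    assert bytes(state.ref) == b"AACGTT"
    assert state.end == 6 and not state.wrapped


def test_append_wraps_circularly():
    # limit 8, 6 bytes present; appending ACGT (8 bytes with its RC) puts
    # 2 bytes at 6..8 and wraps the remaining 6 to 0..6
    params = _params(ref_limit=8)
    state = ReferenceState(params)
    state.append_raw(b"AACGTT")
    state.append_contig(b"ACGT")           # chunk = ACGTACGT
    assert state.wrapped
    assert state.extent == 8
    assert bytes(state.ref) == b"GTACGTAC"
    assert state.write_pos == 6


def test_wrap_extent_never_exceeds_limit():
    params = _params(ref_limit=64)
    state = ReferenceState(params)
    rng = np.random.default_rng(0)
    for _ in range(20):
        state.append_contig(random_seq(rng, int(rng.integers(1, 100))))
        assert state.extent <= 64


# ----------------------------------------------------------- collections

def test_single_genome_default_mode_travels_as_literals(small_params):
    g = GenomeFile("g.fa", [Contig(b"c1", b"ACGTAACC"), Contig(b"c2", b"")])
    s = encode_collection([g], small_params)
    assert s.token_kinds == [0]            # one literal run, empty contig none
    assert bytes(s.literal_bytes) == b"ACGTAACC"
    assert s.appended_flags == [False, False]


def test_max_mode_first_contig_literal_then_appended():
    g = GenomeFile("g.fa", [Contig(b"c", b"ACGT" * 100)])
    params = _params(mode="max")
    s = encode_collection([g], params)
    assert s.token_kinds == [0]
    assert s.appended_flags == [True]


def test_empty_collection_yields_empty_streams(small_params):
    s = encode_collection([], small_params)
    assert s.filenames == [] and s.token_kinds == []


def test_identical_genomes_mostly_match_covered(small_params):
    g = make_collection(SimParams(ancestor_len=30_000, n_genomes=10, seed=4,
                                  snp_rate=0.0, indel_rate=0.0,
                                  inversion_rate=0.0, contigs_per_genome=1))
    s = encode_collection(g, small_params)
    total = sum(x.total_length for x in g)
    matched = sum(s.lengths)
    assert matched >= 0.9 * total


def test_encoding_is_deterministic(small_collection, small_params):
    from mbgcpy.archive import serialize_streams
    a = serialize_streams(encode_collection(small_collection, small_params))
    b = serialize_streams(encode_collection(small_collection, small_params))
    assert a == b


def test_rc_matching_covers_inverted_segments():
    rng = np.random.default_rng(9)
    base = random_seq(rng, 4000)
    inverted = base[:1000] + reverse_complement(base[1000:3000]) + base[3000:]
    g1 = GenomeFile("a.fa", [Contig(b"c", base)])
    g2 = GenomeFile("b.fa", [Contig(b"c", inverted)])
    for rc_on in (True, False):
        params = EncoderParams(k=16, stride=1, table_bits=18, rc_enabled=rc_on)
        s = encode_collection([g1, g2], params)
        covered = sum(s.lengths)
        if rc_on:
            assert covered >= 3900      # inversion matched via the RC copy
        else:
            assert covered <= 2100      # inversion stays literal
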