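"""Nucleotide-sequence primitives shared by the encoder, decoder and tests.

Sequences are plain :class:`bytes` of uppercase symbols (``A C G T N`` plus
tolerated IUPAC ambiguity codes).  All functions here are total on arbitrary
byte strings so that round-trip guarantees never depend on input hygiene.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "reverse_complement",
    "is_valid_seed",
    "hash_kmer",
    "hash_positions",
    "COMPLEMENT",
]

# Full IUPAC complement; every byte not listed maps to itself, which makes
# reverse_complement an involution on arbitrary byte strings.
_PAIRS = {
    b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A",
    b"R": b"Y", b"Y": b"R", b"K": b"M", b"M": b"K",
    b"B": b"V", b"V": b"B", b"D": b"H", b"H": b"D",
    # N, S, W, U(->A? no: U pairs with A in RNA, but DNA input is expected;
    # left as self-map), X etc. fall through to identity except listed above.
}

_table = bytearray(range(256))
for _a, _b in _PAIRS.items():
    _table[_a[0]] = _b[0]
    _table[_b[0]] = _a[0]
COMPLEMENT = bytes(_table)
del _table, _a, _b

# 2-bit codes for seed symbols; 255 marks a byte that cannot appear in a seed.
CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    CODE_LUT[_c] = _i
del _i, _c

_MASK64 = 0xFFFFFFFFFFFFFFFF


def reverse_complement(s: bytes) -> bytes:
    """Return the reverse complement of *s* (A<->T, C<->G, IUPAC-aware).

    Unknown bytes map to themselves, so ``reverse_complement`` is an
    involution on every byte string.
    """
    return s.translate(COMPLEMENT)[::-1]


def is_valid_seed(kmer: bytes, k: int | None = None) -> bool:
    """True iff *kmer* consists solely of A/C/G/T (usable as a hash seed).

    If *k* is given the k-mer length is checked and a mismatch raises
    ``ValueError`` (a usage error, not a data error).
    """
    if k is not None and len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got {len(kmer)} symbols")
    return all(CODE_LUT[b] != 255 for b in kmer)


def _splitmix64(v: int) -> int:
    v = (v + 0x9E3779B97F4A7C15) & _MASK64
    v = ((v ^ (v >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    v = ((v ^ (v >> 27)) * 0x94D049BB133111EB) & _MASK64
    return v ^ (v >> 31)


def hash_kmer(kmer: bytes, table_bits: int) -> int:
    """Hash a valid seed to a slot in ``[0, 2**table_bits)``.

    The k-mer is packed 2 bits per symbol into a 64-bit word (for k > 32 the
    leading symbols fall off; downstream verification against the reference
    makes any resulting extra collisions harmless) and mixed with a
    splitmix64 finalizer.  Deterministic and stateless.
    """
    v = 0
    for b in kmer:
        c = CODE_LUT[b]
        if c == 255:
            raise ValueError("seed contains a non-ACGT symbol")
        v = ((v << 2) | int(c)) & _MASK64
    return _splitmix64(v) & ((1 << table_bits) - 1)


def hash_positions(codes: np.ndarray, positions: np.ndarray, k: int,
                   table_bits: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ``hash_kmer`` over many start positions of one sequence.

    *codes* is the 2-bit code array (255 = invalid) of the whole sequence;
    *positions* are k-mer start offsets with ``pos + k <= len(codes)``.
    Returns ``(slots, valid)`` where invalid seeds get an arbitrary slot and
    ``valid[i]`` is False.  Bit-identical to the scalar ``hash_kmer``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    v = np.zeros(len(positions), dtype=np.uint64)
    valid = np.ones(len(positions), dtype=bool)
    for i in range(k):
        c = codes[positions + i]
        valid &= c != 255
        v = (v << np.uint64(2)) | (c & np.uint8(3)).astype(np.uint64)
    # splitmix64, vectorised (unsigned arithmetic wraps silently)
    v = v + np.uint64(0x9E3779B97F4A7C15)
    v = (v ^ (v >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    v = (v ^ (v >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    v ^= v >> np.uint64(31)
    slots = (v & np.uint64((1 << table_bits) - 1)).astype(np.int64)
    return slots, valid
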