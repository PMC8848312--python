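"""Brute-force greedy LZ oracle, independent of the engine under test.

At every scan position the oracle searches the whole reference by direct
byte comparison for the longest match of length >= k; on success it covers
those symbols and jumps past them, otherwise it advances one symbol.  It is
quadratic and only meant for desk-scale reference strings.
"""

from __future__ import annotations


def greedy_coverage(ref: bytes, contig: bytes, k: int) -> int:
    """Symbols of *contig* covered by greedy leftmost >=k matches into *ref*."""
    pos, covered, L = 0, 0, len(contig)
    while pos + k <= L:
        best = 0
        kmer = contig[pos:pos + k]
        start = ref.find(kmer)
        while start != -1:
            length = k
            while (pos + length < L and start + length < len(ref)
                   and ref[start + length] == contig[pos + length]):
                length += 1
            if length > best:
                best = length
            start = ref.find(kmer, start + 1)
        if best:
            covered += best
            pos += best
        else:
            pos += 1
    return covered
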