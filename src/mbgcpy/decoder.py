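"""Exact inverse of the encoder: stream replay with REF reconstruction.

The decoder walks the streams contig by contig, concatenating literal runs
and REF substrings, and grows its own REF copy with the identical
append/wrap policy.  Append decisions are read from the per-contig flag
stream rather than recomputed, so correctness depends only on streams and
flags — the decoder never consults a hash index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .archive import CorruptArchiveError, read_archive
from .encoder import (EncoderParams, ReferenceState, StreamSet,
                      init_reference_empty)
from .fasta import Contig, GenomeFile, write_fasta

__all__ = ["DecodeState", "decode_contig", "decode_streams", "decode_collection"]


@dataclass
class DecodeState:
    """Replayed REF plus cursors into every stream of the StreamSet."""

    streams: StreamSet
    ref: ReferenceState
    contig_i: int = 0   # global contig index (headers, flags, token_counts)
    token_i: int = 0    # global token index (token_kinds)
    match_i: int = 0    # offsets / lengths cursor
    lit_i: int = 0      # literal_lens cursor
    lit_byte: int = 0   # literal_bytes cursor


def decode_contig(state: DecodeState) -> Contig:
    """Reproduce the next contig and advance every cursor it consumes."""
    s = state.streams
    if state.contig_i >= len(s.headers):
        raise CorruptArchiveError("contig streams exhausted")
    header = s.headers[state.contig_i]
    n_tokens = s.token_counts[state.contig_i]
    parts: list[bytes] = []
    for _ in range(n_tokens):
        if state.token_i >= len(s.token_kinds):
            raise CorruptArchiveError("token stream exhausted")
        kind = s.token_kinds[state.token_i]
        state.token_i += 1
        if kind:
            if state.match_i >= len(s.offsets):
                raise CorruptArchiveError("match stream exhausted")
            off = s.offsets[state.match_i]
            length = s.lengths[state.match_i]
            state.match_i += 1
            if off + length > state.ref.extent:
                raise CorruptArchiveError(
                    f"match [{off}, {off + length}) beyond REF extent "
                    f"{state.ref.extent}")
            parts.append(bytes(state.ref.ref[off:off + length]))
        else:
            if state.lit_i >= len(s.literal_lens):
                raise CorruptArchiveError("literal stream exhausted")
            length = s.literal_lens[state.lit_i]
            state.lit_i += 1
            if state.lit_byte + length > len(s.literal_bytes):
                raise CorruptArchiveError("literal bytes exhausted")
            parts.append(bytes(
                s.literal_bytes[state.lit_byte:state.lit_byte + length]))
            state.lit_byte += length
    state.contig_i += 1
    return Contig(header, b"".join(parts))


def decode_streams(s: StreamSet,
                   on_contig: Optional[Callable] = None) -> list[GenomeFile]:
    """Replay a full StreamSet back into the original genome collection.

    In default mode the first file is rebuilt from literals alone and then
    seeds REF (concatenated contigs followed by the reverse complement);
    afterwards the per-contig appended flags drive REF growth exactly as
    during encoding.
    """
    params = s.params
    state = DecodeState(streams=s,
                        ref=init_reference_empty(params, with_index=False))
    out: list[GenomeFile] = []
    for fi, (name, n_contigs) in enumerate(zip(s.filenames, s.contig_counts)):
        g = GenomeFile(name=name)
        seed_file = params.mode == "default" and fi == 0
        for ci in range(n_contigs):
            contig = decode_contig(state)
            g.contigs.append(contig)
            if not seed_file and s.appended_flags[state.contig_i - 1]:
                state.ref.append_contig(contig.seq)
            if on_contig is not None:
                on_contig(fi, ci, state.ref)
        if seed_file:
            state.ref.append_contig(b"".join(c.seq for c in g.contigs))
        out.append(g)
    return out


def _safe_relative(name: str) -> Path:
    p = Path(name)
    if p.is_absolute() or ".." in p.parts:
        raise CorruptArchiveError(f"unsafe member path in archive: {name!r}")
    return p


def decode_collection(archive_path: str | Path, out_dir: str | Path,
                      line_width: int = 0, gzip_out: bool = False) -> list[Path]:
    """Decompress an archive, recreating every file under *out_dir*.

    ``line_width`` inserts EOLs every that many symbols (0 = none); the
    original EOL layout is deliberately not preserved.  Subdirectories are
    recreated from the stored relative names.
    """
    s = read_archive(archive_path)
    genomes = decode_streams(s)
    out = Path(out_dir)
    written: list[Path] = []
    for g in genomes:
        dest = out / _safe_relative(g.name)
        gz = gzip_out or dest.suffix == ".gz"
        if gzip_out and dest.suffix != ".gz":
            dest = dest.with_name(dest.name + ".gz")
        write_fasta(g, dest, line_width=line_width, gzip_out=gz)
        written.append(dest)
    return written
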