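"""Container format: stream serialization, LZMA back-end, archive file I/O.

Every stream of a :class:`~mbgcpy.encoder.StreamSet` is serialized to a
deterministic byte string (integers as unsigned LEB128 varints, flags
bit-packed little-endian, text NUL-separated), compressed independently
with LZMA, and written into a small directory-based container.  The full
encoder parameter set is echoed in the header, so decoding needs no
external configuration.  See FORMAT.md for the bit-exact layout.
"""

from __future__ import annotations

import lzma
from pathlib import Path
from typing import Iterable

from .encoder import EncoderParams, StreamSet

__all__ = [
    "MAGIC", "VERSION",
    "ArchiveError", "BadMagicError", "BadVersionError",
    "TruncatedArchiveError", "CorruptArchiveError",
    "write_varint", "read_varint", "serialize_streams", "deserialize_streams",
    "backend_compress", "backend_decompress", "write_archive", "read_archive",
]

MAGIC = b"MBGCpy\x00"
VERSION = 1

BACKEND_LZMA = 1

# stable stream ids (directory order is ascending id)
_STREAMS = [
    "filenames", "contig_counts", "headers", "token_counts", "token_kinds",
    "offsets", "lengths", "literal_lens", "literal_bytes", "appended_flags",
]


class ArchiveError(Exception):
    """Base class for malformed archives."""


class BadMagicError(ArchiveError):
    pass


class BadVersionError(ArchiveError):
    pass


class TruncatedArchiveError(ArchiveError):
    pass


class CorruptArchiveError(ArchiveError):
    pass


def write_varint(value: int, out: bytearray) -> None:
    """Append the unsigned LEB128 encoding of *value*."""
    if value < 0:
        raise ValueError("varints are unsigned")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            out.append(b | 0x80)
        else:
            out.append(b)
            return


def read_varint(buf: bytes, pos: int) -> tuple[int, int]:
    """Decode an unsigned LEB128 varint at *pos*; return (value, new_pos)."""
    value = shift = 0
    while True:
        if pos >= len(buf):
            raise TruncatedArchiveError("varint runs past end of data")
        b = buf[pos]
        pos += 1
        value |= (b & 0x7F) << shift
        if not b & 0x80:
            return value, pos
        shift += 7
        if shift > 70:
            raise CorruptArchiveError("varint too long")


def _pack_varints(values: Iterable[int]) -> bytes:
    out = bytearray()
    for v in values:
        write_varint(v, out)
    return bytes(out)


def _unpack_varints(buf: bytes, count: int) -> list[int]:
    out, pos = [], 0
    for _ in range(count):
        v, pos = read_varint(buf, pos)
        out.append(v)
    if pos != len(buf):
        raise CorruptArchiveError("trailing bytes in integer stream")
    return out


def _pack_bits(flags: Iterable[bool | int]) -> bytes:
    out = bytearray()
    acc = nbits = 0
    for f in flags:
        acc |= (1 if f else 0) << nbits
        nbits += 1
        if nbits == 8:
            out.append(acc)
            acc = nbits = 0
    if nbits:
        out.append(acc)
    return bytes(out)


def _unpack_bits(buf: bytes, count: int) -> list[int]:
    if len(buf) != (count + 7) // 8:
        raise CorruptArchiveError("flag stream has wrong length")
    return [(buf[i >> 3] >> (i & 7)) & 1 for i in range(count)]


def serialize_streams(s: StreamSet) -> dict[str, bytes]:
    """Turn a StreamSet into named deterministic byte strings (bijective)."""
    return {
        "filenames": b"\x00".join(n.encode("utf-8") for n in s.filenames),
        "contig_counts": _pack_varints(s.contig_counts),
        "headers": b"\x00".join(s.headers),
        "token_counts": _pack_varints(s.token_counts),
        "token_kinds": _pack_bits(s.token_kinds),
        "offsets": _pack_varints(s.offsets),
        "lengths": _pack_varints(s.lengths),
        "literal_lens": _pack_varints(s.literal_lens),
        "literal_bytes": bytes(s.literal_bytes),
        "appended_flags": _pack_bits(s.appended_flags),
    }


def deserialize_streams(raw: dict[str, bytes], params: EncoderParams) -> StreamSet:
    """Inverse of :func:`serialize_streams`."""
    s = StreamSet(params=params)
    n_files_blob = raw["filenames"]
    s.contig_counts = []
    # file count is implied by the contig_counts stream
    pos = 0
    buf = raw["contig_counts"]
    while pos < len(buf):
        v, pos = read_varint(buf, pos)
        s.contig_counts.append(v)
    n_files = len(s.contig_counts)
    s.filenames = ([p.decode("utf-8") for p in n_files_blob.split(b"\x00")]
                   if n_files else [])
    if len(s.filenames) != n_files:
        raise CorruptArchiveError("filename count does not match file count")
    n_contigs = sum(s.contig_counts)
    s.headers = raw["headers"].split(b"\x00") if n_contigs else []
    if len(s.headers) != n_contigs:
        raise CorruptArchiveError("header count does not match contig count")
    s.token_counts = _unpack_varints(raw["token_counts"], n_contigs)
    n_tokens = sum(s.token_counts)
    s.token_kinds = _unpack_bits(raw["token_kinds"], n_tokens)
    n_matches = sum(s.token_kinds)
    s.offsets = _unpack_varints(raw["offsets"], n_matches)
    s.lengths = _unpack_varints(raw["lengths"], n_matches)
    s.literal_lens = _unpack_varints(raw["literal_lens"],
                                     n_tokens - n_matches)
    s.literal_bytes = bytearray(raw["literal_bytes"])
    if sum(s.literal_lens) != len(s.literal_bytes):
        raise CorruptArchiveError("literal stream length mismatch")
    s.appended_flags = [bool(b) for b in
                        _unpack_bits(raw["appended_flags"], n_contigs)]
    return s


def backend_compress(raw: bytes, level: int) -> bytes:
    """Compress one stream with LZMA at the given preset (lossless)."""
    return lzma.compress(raw, format=lzma.FORMAT_XZ, preset=level)


def backend_decompress(payload: bytes) -> bytes:
    try:
        return lzma.decompress(payload, format=lzma.FORMAT_XZ)
    except lzma.LZMAError as e:
        raise CorruptArchiveError(f"back-end stream corrupt: {e}") from e


def _params_block(p: EncoderParams) -> bytes:
    out = bytearray()
    for v in (0 if p.mode == "default" else 1, p.k, p.stride, p.m, p.u,
              p.table_bits, p.effective_ref_limit, int(p.rc_enabled),
              int(p.swallow), p.effective_backend_level):
        write_varint(v, out)
    return bytes(out)


def _parse_params_block(buf: bytes, pos: int) -> tuple[EncoderParams, int]:
    vals = []
    for _ in range(10):
        v, pos = read_varint(buf, pos)
        vals.append(v)
    mode_i, k, stride, m, u, table_bits, ref_limit, rc, swallow, level = vals
    try:
        params = EncoderParams(
            k=k, stride=stride, m=m, u=u, table_bits=table_bits,
            ref_limit=ref_limit, rc_enabled=bool(rc),
            mode="max" if mode_i else "default", swallow=bool(swallow),
            backend_level=level)
    except ValueError as e:
        raise CorruptArchiveError(f"invalid parameter block: {e}") from e
    return params, pos


def write_archive(s: StreamSet, path: str | Path) -> int:
    """Write the StreamSet as a container file; returns bytes written."""
    raw = serialize_streams(s)
    level = s.params.effective_backend_level
    head = bytearray()
    head += MAGIC
    head.append(VERSION)
    head += _params_block(s.params)
    write_varint(len(_STREAMS), head)
    payloads = []
    for sid, name in enumerate(_STREAMS):
        comp = backend_compress(raw[name], level)
        head.append(sid)
        head.append(BACKEND_LZMA)
        write_varint(len(raw[name]), head)
        write_varint(len(comp), head)
        payloads.append(comp)
    blob = bytes(head) + b"".join(payloads)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_bytes(blob)
    return len(blob)


def read_archive(path: str | Path) -> StreamSet:
    """Read a container file back into a StreamSet (params echoed inside)."""
    blob = Path(path).read_bytes()
    if len(blob) < len(MAGIC) + 1:
        raise TruncatedArchiveError("file shorter than the archive header")
    if blob[:len(MAGIC)] != MAGIC:
        raise BadMagicError("not an mbgcpy archive (bad magic)")
    pos = len(MAGIC)
    version = blob[pos]
    pos += 1
    if version != VERSION:
        raise BadVersionError(f"unsupported archive version {version}")
    params, pos = _parse_params_block(blob, pos)
    n_streams, pos = read_varint(blob, pos)
    directory = []
    for _ in range(n_streams):
        if pos + 2 > len(blob):
            raise TruncatedArchiveError("stream directory truncated")
        sid, backend = blob[pos], blob[pos + 1]
        pos += 2
        raw_size, pos = read_varint(blob, pos)
        comp_size, pos = read_varint(blob, pos)
        directory.append((sid, backend, raw_size, comp_size))
    raw: dict[str, bytes] = {}
    for sid, backend, raw_size, comp_size in directory:
        if sid >= len(_STREAMS):
            raise CorruptArchiveError(f"unknown stream id {sid}")
        if backend != BACKEND_LZMA:
            raise CorruptArchiveError(f"unknown back-end id {backend}")
        payload = blob[pos:pos + comp_size]
        if len(payload) != comp_size:
            raise TruncatedArchiveError("payload truncated")
        pos += comp_size
        data = backend_decompress(payload)
        if len(data) != raw_size:
            raise CorruptArchiveError("stream size mismatch after decompression")
        raw[_STREAMS[sid]] = data
    missing = set(_STREAMS) - set(raw)
    if missing:
        raise CorruptArchiveError(f"archive lacks streams: {sorted(missing)}")
    return deserialize_streams(raw, params)
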