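"""FASTA collection I/O: plain or gzipped files, header-preserving.

End-of-line bytes inside sequence blocks are normalisation noise: they are
removed on read and re-inserted on write at a user-chosen width, so equality
of :class:`GenomeFile` values is EOL-insensitive by construction.  Header
lines are preserved verbatim (minus the ``>`` and the EOL).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Contig", "GenomeFile", "read_fasta", "write_fasta", "read_collection",
           "FastaFormatError"]


class FastaFormatError(ValueError):
    """Raised when a file does not parse as FASTA."""


@dataclass
class Contig:
    header: bytes          # text after '>' up to EOL, without the EOL
    seq: bytes             # uppercase symbols, no EOL bytes

    def __post_init__(self) -> None:
        if b"\n" in self.header or b"\r" in self.header:
            raise ValueError("contig header contains EOL bytes")


@dataclass
class GenomeFile:
    name: str                          # relative path, as given
    contigs: list[Contig] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(c.seq) for c in self.contigs)


def _open_maybe_gzip(path: str | Path) -> bytes:
    p = Path(path)
    data = p.read_bytes()
    if p.suffix == ".gz" or data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data


def read_fasta(path: str | Path, *, name: str | None = None) -> GenomeFile:
    """Parse one (possibly gzipped) FASTA file into a :class:`GenomeFile`.

    Sequence lines are uppercased and stripped of EOL bytes; blank lines are
    ignored.  A non-empty file whose first non-blank byte is not ``>`` is a
    format error.
    """
    data = _open_maybe_gzip(path)
    g = GenomeFile(name=name if name is not None else str(path))
    header: bytes | None = None
    chunks: list[bytes] = []
    for raw in data.split(b"\n"):
        line = raw.rstrip(b"\r")
        if not line:
            continue
        if line.startswith(b">"):
            if header is not None:
                g.contigs.append(Contig(header, b"".join(chunks)))
            header = line[1:]
            chunks = []
        else:
            if header is None:
                raise FastaFormatError(f"{path}: expected '>' before sequence data")
            chunks.append(line.upper())
    if header is not None:
        g.contigs.append(Contig(header, b"".join(chunks)))
    return g


def write_fasta(g: GenomeFile, path: str | Path, line_width: int = 0,
                *, gzip_out: bool = False) -> None:
    """Write *g* as FASTA; ``line_width == 0`` means one line per sequence.

    ``read_fasta(write_fasta(g, w)) == g`` for every width.
    """
    if line_width < 0:
        raise ValueError("line_width must be >= 0")
    out = bytearray()
    for c in g.contigs:
        out += b">" + c.header + b"\n"
        if line_width == 0 or not c.seq:
            out += c.seq + b"\n"
        else:
            for i in range(0, len(c.seq), line_width):
                out += c.seq[i:i + line_width] + b"\n"
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    payload = gzip.compress(bytes(out), mtime=0) if gzip_out else bytes(out)
    p.write_bytes(payload)


def read_collection(paths: Sequence[str | Path] | None = None,
                    list_file: str | Path | None = None,
                    base_dir: str | Path | None = None) -> list[GenomeFile]:
    """Read an ordered collection of FASTA files.

    Either an explicit ordered *paths* sequence or a *list_file* (one path
    per line, ``#`` comments and blank lines ignored) names the members.
    Names are stored as given (relative to *base_dir* when set).
    """
    if (paths is None) == (list_file is None):
        raise ValueError("give exactly one of paths / list_file")
    if list_file is not None:
        base = Path(base_dir) if base_dir is not None else Path(list_file).parent
        entries: list[str] = []
        for line in Path(list_file).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                entries.append(line)
    else:
        base = Path(base_dir) if base_dir is not None else None
        entries = [str(p) for p in paths]

    out: list[GenomeFile] = []
    for entry in entries:
        full = (base / entry) if base is not None else Path(entry)
        if not full.exists():
            raise FileNotFoundError(f"collection member not readable: {entry}")
        out.append(read_fasta(full, name=entry))
    return out
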