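"""Deterministic generator of bacterial-like genome collections.

The generator emulates the redundancy structure referential compression
exploits: a random ancestor sequence, per-genome point mutations (SNPs),
short indels with geometric lengths, reverse-complemented segmental
inversions, and fragmentation into contigs.  Each genome draws from an
independent RNG substream keyed by ``(seed, genome_index)`` (NumPy PCG64
via ``default_rng``), so a collection is extensible without shifting the
genomes already generated, and fixed seeds give byte-identical files.

This is deliberately not an evolutionary model: no codon structure, GC
skew, repeat families or horizontal transfer — just controlled divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fasta import Contig, GenomeFile, write_fasta
from .seqs import reverse_complement

__all__ = ["SimParams", "generate_ancestor", "derive_genome",
           "generate_collection", "STANDARD_FIXTURES"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic collection.

    Defaults model a desk-scale bacterial collection: a 100 kb ancestor
    (a scaled-down chromosome), 10 genomes at ~0.1% SNP divergence, rare
    short indels, one ~1 kb inversion per genome, a handful of contigs.
    """

    ancestor_len: int = 100_000
    n_genomes: int = 10
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    indel_len_mean: float = 3.0
    inversion_rate: float = 1.0          # expected inversions per genome
    inversion_len: tuple[int, int] = (500, 2000)
    contigs_per_genome: int | tuple[int, int] = (1, 4)
    gzip_fraction: float = 0.0           # fraction of files written as .fa.gz
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.indel_rate, self.gzip_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.ancestor_len < 1 or self.n_genomes < 0:
            raise ValueError("ancestor_len >= 1 and n_genomes >= 0 required")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimParams":
        """Load parameters from a JSON or TOML file mirroring the fields."""
        p = Path(path)
        if p.suffix == ".toml":
            import tomllib
            data = tomllib.loads(p.read_text())
        else:
            data = json.loads(p.read_text())
        if "inversion_len" in data:
            data["inversion_len"] = tuple(data["inversion_len"])
        if isinstance(data.get("contigs_per_genome"), list):
            data["contigs_per_genome"] = tuple(data["contigs_per_genome"])
        return cls(**data)


def generate_ancestor(length: int, seed: int) -> bytes:
    """Uniform i.i.d. sequence over {A,C,G,T}; fixed seed, fixed output."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes()


def _apply_snps(arr: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return arr
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if not len(hits):
        return arr
    code = np.searchsorted(_BASES, arr[hits])  # ACGT sorted, so codes direct
    shift = rng.integers(1, 4, size=len(hits))
    arr = arr.copy()
    arr[hits] = _BASES[(code + shift) % 4]
    return arr


def _apply_indels(seq: bytes, rate: float, len_mean: float, rng) -> bytes:
    if rate <= 0:
        return seq
    n = len(seq)
    sites = np.nonzero(rng.random(n) < rate)[0]
    if not len(sites):
        return seq
    p = min(1.0, 1.0 / max(len_mean, 1.0))
    out: list[bytes] = []
    prev = 0
    for site in sites:
        site = int(site)
        if site < prev:
            continue            # swallowed by a previous deletion
        out.append(seq[prev:site])
        length = int(rng.geometric(p))
        if rng.random() < 0.5:  # deletion
            prev = site + length
        else:                   # insertion
            ins = _BASES[rng.integers(0, 4, size=length)].tobytes()
            out.append(ins)
            prev = site
    out.append(seq[prev:])
    return b"".join(out)


def _apply_inversions(seq: bytes, sim: SimParams, rng) -> bytes:
    count = int(rng.poisson(sim.inversion_rate))
    lo, hi = sim.inversion_len
    for _ in range(count):
        if len(seq) < lo + 1:
            break
        length = int(rng.integers(lo, min(hi, len(seq)) + 1))
        start = int(rng.integers(0, len(seq) - length + 1))
        seq = (seq[:start]
               + reverse_complement(seq[start:start + length])
               + seq[start + length:])
    return seq


def _fragment(seq: bytes, n_contigs: int | tuple[int, int], rng) -> list[bytes]:
    if isinstance(n_contigs, tuple):
        n = int(rng.integers(n_contigs[0], n_contigs[1] + 1))
    else:
        n = int(n_contigs)
    n = max(1, min(n, max(1, len(seq))))
    if n == 1:
        return [seq]
    cuts = np.sort(rng.choice(np.arange(1, len(seq)), size=n - 1,
                              replace=False))
    bounds = [0, *map(int, cuts), len(seq)]
    return [seq[a:b] for a, b in zip(bounds, bounds[1:])]


def derive_genome(ancestor: bytes, sim: SimParams, genome_index: int) -> GenomeFile:
    """Mutate the ancestor into genome *genome_index* and fragment it.

    SNPs, then indels, then inversions, each from the genome's own RNG
    substream; deterministic for fixed (seed, genome_index).
    """
    rng = np.random.default_rng([sim.seed, genome_index])
    arr = np.frombuffer(ancestor, dtype=np.uint8)
    arr = _apply_snps(arr, sim.snp_rate, rng)
    seq = _apply_indels(arr.tobytes(), sim.indel_rate, sim.indel_len_mean, rng)
    seq = _apply_inversions(seq, sim, rng)
    pieces = _fragment(seq, sim.contigs_per_genome, rng)
    name = f"genome_{genome_index:03d}.fa"
    contigs = [
        Contig(f"g{genome_index}_c{j} synthetic len={len(p)}".encode(), p)
        for j, p in enumerate(pieces)
    ]
    return GenomeFile(name=name, contigs=contigs)


def generate_collection(sim: SimParams, out_dir: str | Path,
                        line_width: int = 0) -> list[Path]:
    """Write ``n_genomes`` FASTA files under *out_dir*; returns ordered paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ancestor = generate_ancestor(sim.ancestor_len, sim.seed)
    paths: list[Path] = []
    for i in range(sim.n_genomes):
        g = derive_genome(ancestor, sim, i)
        gz = (np.random.default_rng([sim.seed, i, 7]).random()
              < sim.gzip_fraction)
        name = g.name + ".gz" if gz else g.name
        g = GenomeFile(name=name, contigs=g.contigs)
        dest = out / name
        write_fasta(g, dest, line_width=line_width, gzip_out=gz)
        paths.append(dest)
    return paths


# The repository's standard fixture suite: three desk-scale collections with
# distinct divergence profiles.  "inversion_rich" carries well over 30% of
# its divergence as reverse-complemented segmental inversions, which is the
# designated mechanism for exercising RC-matching.
STANDARD_FIXTURES: dict[str, SimParams] = {
    "snp": SimParams(ancestor_len=50_000, n_genomes=8, seed=11,
                     snp_rate=5e-3, indel_rate=2e-4, inversion_rate=0.0),
    "mixed": SimParams(ancestor_len=50_000, n_genomes=8, seed=12,
                       snp_rate=5e-3, indel_rate=2e-4, inversion_rate=2.0),
    "inversion_rich": SimParams(ancestor_len=50_000, n_genomes=8, seed=13,
                                snp_rate=2e-3, indel_rate=1e-4,
                                inversion_rate=4.0,
                                inversion_len=(1000, 4000)),
}
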