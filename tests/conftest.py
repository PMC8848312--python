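"""Shared fixtures: small deterministic synthetic collections."""

from __future__ import annotations

import numpy as np
import pytest

from mbgcpy import (EncoderParams, GenomeFile, SimParams, derive_genome,
                    generate_ancestor, read_collection, generate_collection)
from mbgcpy.simulate import STANDARD_FIXTURES

_BASES = np.frombuffer(b"ACGT", np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> bytes:
    return _BASES[rng.integers(0, 4, n)].tobytes()


def make_collection(sim: SimParams) -> list[GenomeFile]:
    """In-memory collection (no files) for encoder/decoder tests."""
    ancestor = generate_ancestor(sim.ancestor_len, sim.seed)
    return [derive_genome(ancestor, sim, i) for i in range(sim.n_genomes)]


@pytest.fixture(scope="session")
def small_collection() -> list[GenomeFile]:
    return make_collection(SimParams(ancestor_len=20_000, n_genomes=5, seed=1))


@pytest.fixture(scope="session")
def standard_fixture_collections() -> dict[str, list[GenomeFile]]:
    return {name: make_collection(sim)
            for name, sim in STANDARD_FIXTURES.items()}


@pytest.fixture()
def small_params() -> EncoderParams:
    # desk-scale table keeps per-test memory modest; k=16 suits short fixtures
    return EncoderParams(k=16, table_bits=18)
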