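"""Shared fixtures: small simulated runs reused across test modules."""

from __future__ import annotations

import random

import pytest

from fungits import ReadPair, SimConfig, simulate_reads
from fungits.simdata import default_samples


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def clean_sim():
    """Error- and artifact-free run: 6 species, 3 samples, 150 pairs each."""
    cfg = SimConfig(
        n_species=6,
        samples=default_samples(3),
        reads_per_sample=150,
        per_base_error=0.0,
        chimera_rate=0.0,
        multiprimer_rate=0.0,
        seed=11,
    )
    return simulate_reads(cfg)


@pytest.fixture(scope="session")
def clean_pairs(clean_sim):
    return [ReadPair(a, b) for a, b in zip(clean_sim.r1, clean_sim.r2)]
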