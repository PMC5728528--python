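from __future__ import annotations

import numpy as np
import pytest

from metapair.pipeline import SimulationConfig, build_scenario
from metapair.synthetic import (
    generate_offtarget_library,
    generate_reference_library,
    simulate_paired_reads,
)


@pytest.fixture(scope="session")
def small_library():
    """2 families x 2 genera x 2 species = 8 references."""
    return generate_reference_library(2, 2, 2, seed=7)


@pytest.fixture(scope="session")
def small_scenario():
    """A 3-sample mock community with reads, reused across tests."""
    sim = SimulationConfig(seed=5, n_samples=3, n_parasitoid_taxa=5,
                           reads_per_sample=300, error_rate=0.001,
                           chimera_rate=0.02)
    design, refs, off = build_scenario(sim)
    fwd, rev, manifest = simulate_paired_reads(
        design, refs + off, sim.reads_per_sample, read_len=300,
        error_rate=sim.error_rate, chimera_rate=sim.chimera_rate, seed=sim.seed,
    )
    return sim, design, refs, off, fwd, rev, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
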