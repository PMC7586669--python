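"""Shared fixtures: synthetic datasets generated at test time (no data files)."""

from __future__ import annotations

import numpy as np
import pytest

from texapt.synthetic_data import (
    SimulationConfig,
    build_te_library,
    generate_screen_dataset,
    random_dna,
)

MASTER_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 20 planted positives, 200 negatives."""
    return generate_screen_dataset(SimulationConfig(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for cheap structural tests."""
    return generate_screen_dataset(
        SimulationConfig(seed=MASTER_SEED, n_positive_genes=4, n_negative_genes=9)
    )


@pytest.fixture(scope="session")
def consensus_library():
    """A two-entry synthetic consensus library for reconstruction tests."""
    rng = np.random.default_rng(7)
    return {"consA": random_dna(1500, rng), "consB": random_dna(1200, rng)}
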