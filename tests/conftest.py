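import numpy as np
import pandas as pd
import pytest

from mctamap.simulate import SimulationConfig, generate_reference_panel


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down world (fewer markers, 3e5 reads) for fast unit tests."""
    return SimulationConfig(
        markers_per_tissue=(6, 2, 2, 3, 3, 3, 2, 2),
        total_mapped_reads=300_000,
        n_wbc_training=29,
        n_pairs=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_reference_panel(small_config)


@pytest.fixture(scope="session")
def decoy_bundle():
    """Small panel salted with one decoy per failure mode (far CpG,
    shared-tissue low tau, WBC-leaky) for selection tests."""
    cfg = SimulationConfig(
        markers_per_tissue=(6, 2, 2, 3, 3, 3, 2, 2),
        total_mapped_reads=300_000,
        n_decoy_far=3,
        n_decoy_shared=3,
        n_decoy_leaky=3,
        seed=23,
    )
    return generate_reference_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
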