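"""Shared fixtures: one small synthetic trial reused across test modules."""

import numpy as np
import pytest

import sparsemet as sm


@pytest.fixture(scope="session")
def small_config() -> sm.SimConfig:
    """50 genotypes x 5 environments with substantial G x E."""
    return sm.SimConfig(
        n_genotypes=50,
        n_environments=5,
        n_markers=300,
        n_blocks_per_rep=5,
        seed=42,
        variance_components={
            "t": dict(g=2.0, gxe=1.5, block_in_rep=0.3, error=0.8)
        },
        trait_means={"t": [10.0, 12.0, 9.0, 11.0, 10.5]},
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sm.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_grm(small_dataset) -> sm.GRM:
    markers, _, _ = small_dataset
    return sm.grm(markers)


@pytest.fixture(scope="session")
def small_blups(small_dataset):
    _, _, plots = small_dataset
    return sm.adjusted_phenotypes(plots)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
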