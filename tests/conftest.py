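"""Shared fixtures: small synthetic worlds and fitted pipelines."""

import numpy as np
import pytest

from bioregions.pipeline import BioregionalizationModel
from bioregions.synthetic import NoiseConfig, WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_config() -> WorldConfig:
    """A fast three-province world for unit tests."""
    return WorldConfig(
        n_provinces=3,
        cells_per_province=6,
        species_per_province=30,
        genus_pool_size=30,
        occurrences_per_cell=60.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def noiseless_config(small_config) -> WorldConfig:
    from dataclasses import replace

    return replace(small_config, noise=NoiseConfig.none(), detection_prob=1.0)


@pytest.fixture(scope="session")
def small_results(small_config):
    """A fitted pipeline on the small world (noise included)."""
    model = BioregionalizationModel.from_synthetic(
        small_config, seed=42, n_clusters=6, rarefy=False
    )
    return model.fit()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
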