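import numpy as np
import pytest

from ionrbe import (
    NucleusGeometry,
    build_territories,
    human_karyotype,
    toy_karyotype,
)
from ionrbe.survival import TerritoryPool


@pytest.fixture(scope="session")
def small_geometry() -> NucleusGeometry:
    """Coarse small nucleus for fast unit tests."""
    return NucleusGeometry(radius_um=3.0, height_um=3.0, voxel_um=0.5)


@pytest.fixture(scope="session")
def toy_config(small_geometry):
    return build_territories(toy_karyotype(), small_geometry, seed=7)


@pytest.fixture(scope="session")
def default_geometry() -> NucleusGeometry:
    return NucleusGeometry()


@pytest.fixture(scope="session")
def human_config(default_geometry):
    return build_territories(human_karyotype(), default_geometry, seed=42)


@pytest.fixture(scope="session")
def human_pool(default_geometry):
    """Small territory pool shared by the slower survival tests."""
    return TerritoryPool(human_karyotype(), default_geometry, seed=99, n_configs=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
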