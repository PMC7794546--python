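import numpy as np
import pytest

from spectune.datasets import SpectraDataset, SyntheticConfig, WavelengthGrid, downsample, generate
from spectune.space import default_space, optimal_lucas_config


@pytest.fixture(scope="session")
def small_dataset() -> SpectraDataset:
    """120 synthetic samples on the downsampled 211-point grid."""
    ds = generate(SyntheticConfig(n_samples=120, seed=3))
    return downsample(ds, 20)


@pytest.fixture(scope="session")
def full_space():
    return default_space(n_samples=17607)


@pytest.fixture(scope="session")
def optimal_config():
    return optimal_lucas_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_grid() -> WavelengthGrid:
    return WavelengthGrid()
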