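import numpy as np
import pandas as pd
import pytest

from ichnostats import synthetic
from ichnostats.synthetic import PopulationConfig


@pytest.fixture(scope="session")
def default_config() -> PopulationConfig:
    return PopulationConfig(seed=42)


@pytest.fixture(scope="session")
def reference_table(default_config) -> pd.DataFrame:
    """Full default synthetic reference table (~490 prints, 41 subjects)."""
    subjects = synthetic.generate_population(default_config)
    return synthetic.generate_footprints(subjects, default_config)


@pytest.fixture(scope="session")
def profile_pool() -> pd.DataFrame:
    """Pure multivariate-normal profile pool: 41 subjects x 12 prints."""
    return synthetic.generate_profile_pool(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
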