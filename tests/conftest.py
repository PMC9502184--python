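import numpy as np
import pytest

from spoilsense import SyntheticConfig, generate_study_design


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: fewer sampling days, 2 replicates, coarse grid kept."""
    return SyntheticConfig(days=(0.0, 1.0, 3.0, 5.0, 7.0), replicates=2, seed=123)


@pytest.fixture(scope="session")
def small_records(small_config):
    return generate_study_design(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20220918)
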