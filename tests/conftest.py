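import numpy as np
import pytest

from footmorph import StudyConfig, build_volume_records, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A reduced study (fast to simulate) with the default noise structure."""
    return StudyConfig(n_feet_pf=10, n_feet_nonpf=16, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return build_volume_records(simulate_study(small_config))


@pytest.fixture(scope="session")
def default_dataset():
    """One default-size study (18 PF / 38 non-PF feet), volumes attached."""
    return build_volume_records(simulate_study(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
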