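import numpy as np
import pytest

from phenodecouple.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-strain synthetic cohort shared across tests (read-only)."""
    config = SyntheticConfig(n_strains=20, n_clades=4, seed=3)
    truth, plate = generate_dataset(config)
    return config, truth, plate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
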