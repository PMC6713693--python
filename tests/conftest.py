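import numpy as np
import pytest

from fatkinetics.cohort import default_config, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def cohort_df():
    """One default 16-subject cohort, shared across tests."""
    return generate_cohort(default_config(rng_seed=7))
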