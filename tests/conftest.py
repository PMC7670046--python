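import numpy as np
import pytest

from dopplergait import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small cohort on a small canvas for fast pipeline-level tests."""
    return simulate_dataset(10, 14, rng_seed=3, canvas=(64, 64))


@pytest.fixture(scope="session")
def cohort_dataset():
    """Full-size default cohort: 56 apathy + 122 non-apathy, 256x256."""
    return simulate_dataset(rng_seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
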