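import numpy as np
import pytest

from chains4d import default_library


@pytest.fixture(scope="session")
def stats():
    """The default shift-statistics library shared across the suite."""
    return default_library()


@pytest.fixture(scope="session")
def small_stats():
    """A lighter library for tests that sweep many spin systems."""
    return default_library(n_per_type=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
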