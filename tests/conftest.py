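import numpy as np
import pytest

import codasub as cs

TRUTH_KINDS = ("linear", "log2", "ilr")


@pytest.fixture(scope="session")
def fixed_truths():
    """Default calibrated truth mechanisms for the time-use scenario."""
    return {k: cs.default_truth(k, "fixed") for k in TRUTH_KINDS}


@pytest.fixture(scope="session")
def variable_truths():
    """Default calibrated truth mechanisms for the dietary scenario."""
    return {k: cs.default_truth(k, "variable") for k in TRUTH_KINDS}


@pytest.fixture(scope="session")
def fixed_data():
    return cs.simulate_fixed_total(n=800, seed=5)


@pytest.fixture(scope="session")
def variable_data():
    return cs.simulate_variable_total(n=800, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
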