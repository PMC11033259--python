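import numpy as np
import pytest

from loadtrf import FrequencyTable, LagSpec


@pytest.fixture(scope="session")
def lag_spec():
    return LagSpec()  # -200 ... 1000 ms at 250 Hz


@pytest.fixture(scope="session")
def lexicon():
    return FrequencyTable({
        "the": 6.329, "cat": 3.33, "sat": 3.1, "on": 5.6, "mat": 2.4,
        "cortex": 2.02,
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
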