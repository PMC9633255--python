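import numpy as np
import pytest
from hypothesis import settings

import dsirlab as d

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return d.load_table()


@pytest.fixture(scope="session")
def ka_token():
    return d.make_token("ka", seed=1)


@pytest.fixture(scope="session")
def white_token():
    rng = np.random.default_rng(7)
    return d.AudioToken(rng.standard_normal(d.SAMPLE_RATE // 2))
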