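import numpy as np
import pytest

from predictivity import load_property_table


@pytest.fixture(scope="session")
def table4():
    return load_property_table("table4")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
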