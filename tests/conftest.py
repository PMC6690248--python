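import numpy as np
import pytest

from mirest.sequence_io import load_table1, load_table2


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
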