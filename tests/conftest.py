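import numpy as np
import pytest

from dropletmd.synthetic import gen_test_parameters


@pytest.fixture(scope="session")
def params():
    """Seeded synthetic parameter tables with the model constants fixed."""
    return gen_test_parameters(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
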