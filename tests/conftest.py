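import numpy as np
import pytest

from carpool.simulate import ScreenDesign, make_default_library


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_library():
    return make_default_library(n_domains=6, n_potent=2, n_inhibitory=1, seed=7)


@pytest.fixture
def small_design():
    return ScreenDesign(
        donors=("donor1", "donor2"),
        replicates=2,
        cells_per_sample=5000,
        read_depth=20000,
        seed=7,
    )
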