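import numpy as np
import pytest

from popout.layout import ChannelLayout
from popout.synthetic import build_stimulus_pool, make_forward_trf


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout.load_default()


@pytest.fixture(scope="session")
def trf(layout):
    return make_forward_trf(layout)


@pytest.fixture(scope="session")
def small_pool():
    """5-pair (10-sentence) pool: one pair per list."""
    return build_stimulus_pool(5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
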