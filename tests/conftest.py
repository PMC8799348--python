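import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_window(rng):
    """A 16-channel, 300-sample window of band-limited-ish noise."""
    from emgcaps import SignalWindow

    return SignalWindow(rng.standard_normal((16, 300)), fs=1000.0, label=2)
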