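import numpy as np
import pytest

from striatumkit import synthkit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calcium_kernel():
    """Single-AP calcium transient template at the default 15 Hz frame rate."""
    return synthkit.make_calcium_kernel(rise=0.05, decay=0.5, peak=0.08, sampling_rate=15.0)


@pytest.fixture
def quiet_cfg():
    return synthkit.SimConfig(seed=7, sampling_rate=15.0, duration=6.0, noise_sd=0.0)
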