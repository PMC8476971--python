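import numpy as np
import pytest

from ardsqct import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_spec():
    """A small, noiseless normal-lung phantom spec."""
    return phantom.PhantomSpec(noise_sd_hu=0.0, seed=3)


@pytest.fixture
def ards_spec():
    """A noiseless ARDS-gradient phantom spec crossing all compartments."""
    return phantom.PhantomSpec(
        aeration_profile="ards_gradient", noise_sd_hu=0.0, effusion=True, seed=3
    )
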