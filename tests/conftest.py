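import numpy as np
import pytest

from bbuda.synthetic import PhantomSpec, DomainParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    return PhantomSpec(image_height=32, image_width=32, n_channels=2,
                       region_radius_mean=(4.0, 7.0, 10.0),
                       region_radius_sd=1.0)


@pytest.fixture
def identity_params():
    return DomainParams()


def random_prob_maps(rng, n=2, c=4, h=8, w=8):
    """Valid random probability maps of shape (N, C, H, W)."""
    raw = rng.gamma(1.0, size=(n, c, h, w))
    return raw / raw.sum(axis=1, keepdims=True)
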