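import numpy as np
import pytest
from hypothesis import settings

from microdeblur import (
    DegradationSpec,
    StarPhantomSpec,
    degrade,
    gaussian_psf,
    generate_star_phantom,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def star_small():
    """128-px star chart with 12 spoke pairs (fast test geometry)."""
    return generate_star_phantom(StarPhantomSpec(image_size=128, n_spoke_pairs=12))


@pytest.fixture(scope="session")
def psf11():
    return gaussian_psf(11, 1.5)


@pytest.fixture(scope="session")
def degraded_small(star_small, psf11):
    return degrade(star_small, DegradationSpec(psf=psf11, noise_variance=0.01, rng_seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
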