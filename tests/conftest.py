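import numpy as np
import pytest

import elastonet as en


@pytest.fixture(scope="session")
def small_spec():
    """64x64 phantom with one centred stiff inclusion, mild noise."""
    return en.PhantomSpec(grid_shape=(64, 64), scatterer_density=1.0,
                          inclusions=((0.5, 0.5, 0.2, 0.5),), seed=3)


@pytest.fixture(scope="session")
def small_sequence(small_spec):
    return en.simulate_sequence(small_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and drift-free phantom for exact-compensation checks."""
    return en.PhantomSpec(grid_shape=(64, 64), scatterer_density=1.0,
                          inclusions=((0.5, 0.5, 0.2, 0.5),),
                          lateral_drift=0.0, noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_sequence(clean_spec):
    return en.simulate_sequence(clean_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
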