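import numpy as np
import pytest
from hypothesis import settings

import esomgen as eg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hepta():
    """A seeded draw of the seven-cloud benchmark (n = 212)."""
    return eg.make_hepta(seed=11)


@pytest.fixture(scope="session")
def small_model(hepta):
    """An ESOM on a reduced grid, big enough to organize the seven clouds."""
    return eg.train_esom(hepta, eg.GridSpec(20, 30, True), epochs=15, seed=7)


@pytest.fixture(scope="session")
def small_radius(hepta, small_model):
    return eg.estimate_density_radius(hepta, small_model, seed=3)


@pytest.fixture(scope="session")
def hepta_genset(hepta, small_radius):
    """Hepta augmented tenfold at the pipeline-estimated radius."""
    return eg.generate_data(hepta, small_radius.radius, eg.GenerationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
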