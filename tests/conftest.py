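import numpy as np
import pytest

from revis import synthetic


@pytest.fixture(scope="session")
def sils_small():
    """Three categories x two exemplars at 128 px (fast unit-test substrate)."""
    return synthetic.generate_category_shapes(3, 2, 128, seed=5)


@pytest.fixture(scope="session")
def scenes_small():
    return synthetic.generate_scene_surrogates(8, 128, seed=2)


@pytest.fixture(scope="session")
def sils700():
    """The full-design stimulus substrate: 8 categories x 10 exemplars, 700 px."""
    return synthetic.generate_category_shapes(8, 10, 700, seed=42)


@pytest.fixture(scope="session")
def response_model():
    return synthetic.default_response_model()


@pytest.fixture(scope="session")
def trials_mid(response_model):
    """Moderate simulated dataset: 4 subjects, 100 trials per cell."""
    return synthetic.simulate_trials(response_model, 4, 100, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
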