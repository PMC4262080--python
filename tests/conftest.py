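import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from nrhmc import GaussianPrior, SteadyStatePosterior, fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mapk_model():
    return fixtures.mapk_erk()


@pytest.fixture(scope="session")
def mapk_dataset(mapk_model):
    return fixtures.generate_dataset(mapk_model, fixtures.mapk_design(seed=11))


@pytest.fixture(scope="session")
def mapk_prior(mapk_model):
    return fixtures.default_prior(mapk_model)


@pytest.fixture()
def mapk_posterior(mapk_model, mapk_dataset, mapk_prior):
    return SteadyStatePosterior(mapk_model, mapk_dataset, mapk_prior, backend="newton")


@pytest.fixture(scope="session")
def mma_model():
    return fixtures.insulin_mma()


@pytest.fixture(scope="session")
def mma_dataset(mma_model):
    return fixtures.generate_dataset(mma_model, fixtures.insulin_design("mma", seed=5))


@pytest.fixture(scope="session")
def mma_prior(mma_model):
    return fixtures.default_prior(mma_model)


@pytest.fixture(scope="session")
def toy_model():
    return fixtures.linear_toy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
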