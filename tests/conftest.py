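import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herdyn.model import CompiledModel
from herdyn.parameters import default_parameters
from herdyn.species import enumerate_species

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def species_set():
    return enumerate_species()


@pytest.fixture()
def model(params):
    # function-scoped: tests mutate ``synthesis``
    return CompiledModel(params=params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
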