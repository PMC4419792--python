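import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copiievo as cv

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_saturation_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*saturated pair.*")
        yield


@pytest.fixture(scope="session")
def scaffold():
    """Default 5-supergroup x 4-taxon scaffold."""
    return cv.build_scaffold()


@pytest.fixture(scope="session")
def small_scaffold():
    """Cheaper 5-supergroup x 2-taxon scaffold for simulation-heavy tests."""
    return cv.build_scaffold(cv.ScaffoldConfig(taxa_per_supergroup=2))


@pytest.fixture(scope="session")
def small_sec24_family(small_scaffold):
    scn = cv.load_scenario("sec24")
    scn.root_length = 300
    records, truth = cv.simulate_family(small_scaffold, scn, seed=11)
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
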