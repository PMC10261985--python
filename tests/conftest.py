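import numpy as np
import pytest
from hypothesis import settings

import fibrosim as fs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixtures() -> dict:
    return fs.builtin_fixtures()


@pytest.fixture(scope="session")
def fitted(fixtures) -> fs.RateParameters:
    return fixtures["fitted"]


@pytest.fixture(scope="session")
def placebo(fixtures) -> fs.RateParameters:
    return fixtures["placebo"]


@pytest.fixture(scope="session")
def pioglitazone(fixtures) -> fs.RateParameters:
    return fixtures["pioglitazone"]


@pytest.fixture(scope="session")
def cusi_placebo_initial(fixtures) -> fs.CohortDistribution:
    return fixtures["cusi_placebo_initial"]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
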