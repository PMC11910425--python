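import pytest
from hypothesis import HealthCheck, settings

from metalrisk import ReferenceSet
from metalrisk.datasets import grass_fixture, soil_fixture, water_quality_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def refs():
    return ReferenceSet()


@pytest.fixture(scope="session")
def soil():
    return soil_fixture()


@pytest.fixture(scope="session")
def grass():
    return grass_fixture()


@pytest.fixture(scope="session")
def water_quality():
    return water_quality_fixture()
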