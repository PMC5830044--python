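import pytest
from hypothesis import HealthCheck, settings

from catpop import UrbanCatPopulationModel
from catpop.casestudy import GUELPH

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def guelph_model():
    """Guelph case-study model under the default (calibrated) variant."""
    return UrbanCatPopulationModel(GUELPH)


@pytest.fixture(scope="session")
def guelph_results(guelph_model):
    results = guelph_model.fit()
    assert results.converged
    return results


@pytest.fixture(scope="session")
def guelph_elasticities_fd(guelph_results):
    return guelph_results.elasticities(method="finite-difference", delta=1e-3)


@pytest.fixture(scope="session")
def guelph_elasticities_implicit(guelph_results):
    return guelph_results.elasticities(method="implicit")
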