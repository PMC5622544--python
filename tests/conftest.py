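import pytest
from hypothesis import HealthCheck, settings

from oncoreg.ontology import load_ontology
from oncoreg.rdf_store import transform
from oncoreg.simulate import load_sim_config, simulate_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def onto():
    return load_ontology()


@pytest.fixture(scope="session")
def stack(onto):
    return load_sim_config(ontology=onto)


@pytest.fixture(scope="session")
def registry60(stack):
    registry, _ = simulate_cohort(stack, 60, seed=11)
    return registry


@pytest.fixture(scope="session")
def store60(registry60, onto):
    return transform(registry60, ontology=onto)


@pytest.fixture(scope="session")
def registry200(stack):
    registry, _ = simulate_cohort(stack, 200, seed=23)
    return registry


@pytest.fixture(scope="session")
def store200(registry200, onto):
    return transform(registry200, ontology=onto)


@pytest.fixture(scope="session")
def registry500(stack):
    registry, _ = simulate_cohort(stack, 500, seed=7)
    return registry


@pytest.fixture(scope="session")
def store500(registry500, onto):
    return transform(registry500, ontology=onto)
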