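import pytest
from hypothesis import HealthCheck, settings

import mitorearrange as mr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def refs() -> dict:
    return mr.load_reference_orders()


@pytest.fixture(scope="session")
def limulus(refs):
    return refs["L_polyphemus"]


@pytest.fixture(scope="session")
def subspinipes(refs):
    return refs["S_subspinipes"]


@pytest.fixture(scope="session")
def dehaani(refs):
    return refs["S_dehaani"]


@pytest.fixture(scope="session")
def mutilans(refs):
    return refs["S_mutilans"]


@pytest.fixture(scope="session")
def marmoratus(refs):
    return refs["M_marmoratus"]


@pytest.fixture(scope="session")
def mini_record():
    return mr.synthetic_record(seed=7)
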