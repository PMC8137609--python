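import pytest
from hypothesis import HealthCheck, settings

import dentage

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def models():
    return dentage.load_builtin("modified_polynomials")


@pytest.fixture(scope="session")
def demirjian_tables():
    return dentage.load_builtin("demirjian")


@pytest.fixture(scope="session")
def willems_tables():
    return dentage.load_builtin("willems")


@pytest.fixture(scope="session")
def reference_tables():
    return dentage.load_builtin("reference_tables")
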