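import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fx():
    from comnet.fixtures import make_fixtures

    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def ref_pv():
    from comnet import reference_parameters

    return reference_parameters()
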