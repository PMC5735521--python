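import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def m10_curve():
    from avtpace import build_curve

    return build_curve("M10", 130, 220, 10)


@pytest.fixture(scope="session")
def m20_curve():
    from avtpace import build_curve

    return build_curve("M20", 130, 210, 10)
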