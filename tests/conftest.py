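import pytest
from hypothesis import HealthCheck, settings

from hopfdna import ElasticConstants

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> ElasticConstants:
    """Canonical B-DNA elastic constants: lp=50 nm, lt=95 nm, 300 K."""
    return ElasticConstants()
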