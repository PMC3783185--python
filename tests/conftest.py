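import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ldimap import refs
from ldimap.coords import Reference


@pytest.fixture(scope="session")
def ref() -> Reference:
    return refs.wt_reference()


@pytest.fixture(scope="session")
def wt_model(ref):
    return refs.wt_structure_model(ref)
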