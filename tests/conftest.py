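import pytest
from hypothesis import settings

from icecurve import SoluteSpec, SolutionComposition, load_registry

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def glucose15(registry):
    return SolutionComposition.single(registry.get("glucose"), 15.0)


@pytest.fixture
def glucose(registry):
    return registry.get("glucose")
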