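import pytest
from hypothesis import settings

from meropk import PkParameters, TargetDefinition

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def pk_default() -> PkParameters:
    """Typical ICU meropenem parameters: CL 7.1 L/h, V 25 L."""
    return PkParameters(clearance=7.1, volume=25.0)


@pytest.fixture
def target_default() -> TargetDefinition:
    return TargetDefinition()
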