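import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from fractoc.formulas import get_material
from fractoc.sedimentation import (
    WATER_20C,
    CentrifugeRun,
    ParticleSpec,
    SuspensionComponent,
)


@pytest.fixture(scope="session")
def ps():
    return get_material("PS")


@pytest.fixture(scope="session")
def water():
    return WATER_20C


@pytest.fixture(scope="session")
def c1_run():
    """First reference spin: 1042-1976 g gradient, 60 mm column, 14 min."""
    return CentrifugeRun.from_rcf_gradient(1042.0, 1976.0, 60.0, 14 * 60.0)


@pytest.fixture(scope="session")
def c2_run():
    """Second reference spin: 1668-3161 g gradient, 60 mm column, 30 min."""
    return CentrifugeRun.from_rcf_gradient(1668.0, 3161.0, 60.0, 30 * 60.0)


@pytest.fixture(scope="session")
def ps_mixture(ps):
    """Equimassic 5/5/5 mg/L mixture of 200/500/1000 nm polystyrene."""
    return [
        SuspensionComponent(ParticleSpec.from_size(d, "nm", 1.05, ps), 5.0)
        for d in (200.0, 500.0, 1000.0)
    ]
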