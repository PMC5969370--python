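import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from triage24 import CasualtyRecord, LSIRegistry, load_default_lsi_registry


@pytest.fixture(scope="session")
def lsi_registry() -> LSIRegistry:
    return load_default_lsi_registry()


def make_record(**kwargs) -> CasualtyRecord:
    """A fully observed, physiologically normal casualty, overridable per field."""
    defaults = dict(
        id="r0",
        can_walk=False,
        catastrophic_haemorrhage=False,
        breathing_after_airway_opened=True,
        rr_bpm=16,
        hr_bpm=80,
        gcs_total=15,
        avpu="A",
        interventions=frozenset(),
    )
    defaults.update(kwargs)
    return CasualtyRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record
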