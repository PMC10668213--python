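import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


from mazekit.geometry import ZoneSpec
from mazekit.engine import SessionConfig


@pytest.fixture
def three_zone_config() -> SessionConfig:
    """A small linear arrangement: three zones, the middle one rewarded."""
    zones = [
        ZoneSpec(id=1, center=(50.0, 100.0), radius=20.0),
        ZoneSpec(id=2, center=(200.0, 100.0), radius=20.0),
        ZoneSpec(id=3, center=(350.0, 100.0), radius=20.0),
    ]
    return SessionConfig(
        zones=zones,
        active_zone_ids=[1, 2, 3],
        rewarded_zone_ids=[2],
        reward_type="liquid",
        rng_seed=0,
    )
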