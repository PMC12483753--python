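import pytest

from gsrstress import SimulatorConfig, StressLevel

#: rest for 30 s, then 30 s each of minor / high / very-high stress
STANDARD_SCHEDULE = (
    (30.0, 60.0, StressLevel.MINOR),
    (60.0, 90.0, StressLevel.HIGH),
    (90.0, 120.0, StressLevel.VERY_HIGH),
)


@pytest.fixture
def scheduled_config():
    """Factory for a 120 s subject stream covering all four stress states."""

    def make(seed: int, noise_sd: float = 20.0, **overrides) -> SimulatorConfig:
        kwargs = dict(
            seed=seed,
            duration_s=120.0,
            noise_sd=noise_sd,
            stress_schedule=STANDARD_SCHEDULE,
        )
        kwargs.update(overrides)
        return SimulatorConfig(**kwargs)

    return make
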