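import pytest
from hypothesis import HealthCheck, settings

from motoriiv import SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_config() -> SimConfig:
    """Small, fast cohort: 4 stroke + 3 healthy, 6 trials, short window."""
    return SimConfig(
        n_stroke=4,
        n_healthy=3,
        n_trials=6,
        move_window_s=1.5,
        onset_delay_range_s=(0.15, 0.3),
        seed=7,
    )


@pytest.fixture
def noise_free_config() -> SimConfig:
    """Deterministic on-target pulses: no noise, no drift, no bias."""
    return SimConfig(
        n_stroke=1,
        n_healthy=1,
        n_trials=3,
        move_window_s=2.0,
        group_mean_bias={"stroke": (1.0, 1.0), "healthy": (1.0, 1.0)},
        group_trial_sd={"stroke": (0.0, 0.0), "healthy": (0.0, 0.0)},
        drift_per_trial={"stroke": (0.0, 0.0), "healthy": (0.0, 0.0)},
        participant_mean_sd=(0.0, 0.0),
        noise_multiplier_range=(1.0, 1.0),
        baseline_noise_sd=0.0,
        outlier_rate=0.0,
        onset_delay_range_s=(0.5, 0.5),
        seed=3,
    )
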