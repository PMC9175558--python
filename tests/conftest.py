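import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def screen_dataset():
    """One small simulated screen shared by scoring tests (2 plates)."""
    from suppscreen.synthetic_data import (
        SimulationConfig,
        planted_effects,
        simulate_screen,
    )

    config = SimulationConfig(seed=11, library_size=160, compounds_per_plate=80)
    effects = planted_effects(
        config,
        np.random.default_rng(11),
        suppressor_fraction=0.05,
        n_bypass=4,
        n_colored=2,
        n_toxic=2,
    )
    return simulate_screen(config, effects)


@pytest.fixture(scope="session")
def joined_screen(screen_dataset):
    from suppscreen.plate_model import join_annotations

    return join_annotations(
        screen_dataset.measurements,
        screen_dataset.annotations,
        screen_dataset.library,
    )
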