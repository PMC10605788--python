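import numpy as np
import pytest

import gaitsurf as g
from gaitsurf.simulate import SimulationConfig, SurfaceEffect


def quiet_config(**overrides) -> SimulationConfig:
    """A noiseless, motionless simulation config for exact-identity tests."""
    effects = {s: SurfaceEffect(jitter_sd_deg=0.0) for s in g.Surface}
    defaults = dict(
        surface_effects=effects,
        noise_sd={"Acc": 0.0, "Gyr": 0.0, "Mag": 0.0},
        site_jitter_floor_deg={s: 0.0 for s in g.Site},
        osc_amp_deg=0.0,
        motion_amp=0.0,
        heading_range_deg=0.0,
        missing_sensor_trials=0,
        duration_mean_s=4.0,
        duration_sd_s=0.5,
        duration_min_s=2.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort() -> g.GaitDataset:
    """2 participants x 9 surfaces x 2 trials, short, separable, no missing."""
    cfg = g.separable_config(
        n_participants=2, trials_per_condition=2,
        duration_mean_s=5.0, duration_sd_s=1.0, duration_min_s=3.0, seed=42)
    return g.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def full_design_cohort() -> g.GaitDataset:
    """The full 30 x 9 x 6 factorial design with short stub trials.

    Fold-plan structure depends only on the trial keys, so short durations
    keep this cheap while exercising the complete design.
    """
    cfg = g.default_config(duration_mean_s=1.5, duration_sd_s=0.2,
                           duration_min_s=1.0, missing_sensor_trials=0,
                           seed=17)
    return g.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def quiet_trial() -> g.Trial:
    cfg = quiet_config()
    rng = np.random.default_rng(0)
    profile = g.simulate.sample_profile(cfg, rng)
    return g.simulate.simulate_trial(profile, g.Surface.FE, 4.0, rng, cfg)
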