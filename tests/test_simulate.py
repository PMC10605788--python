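import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gaitsurf as g
from gaitsurf.core import CHANNEL_INDEX, Site, Surface
from gaitsurf.simulate import (
    B_EARTH,
    GRAVITY,
    euler_zyx_matrices,
    inject_missing,
    sample_profile,
    simulate_cohort,
    simulate_trial,
)

from conftest import quiet_config


def _cols(trial, site, names):
    idx = [CHANNEL_INDEX[n] for n in names]
    return trial.data[site][:, idx]


@pytest.fixture(scope="module")
def noisy_trial():
    cfg = g.default_config()
    rng = np.random.default_rng(3)
    profile = sample_profile(cfg, rng)
    return simulate_trial(profile, Surface.CS, 6.0, rng, cfg)


class TestKinematicIdentities:
    """Physical inter-channel identities hold exactly on generated data."""

    @pytest.mark.parametrize("site", list(Site))
    def test_velocity_increment_is_acc_over_rate(self, noisy_trial, site):
        acc = _cols(noisy_trial, site, ["Acc_X", "Acc_Y", "Acc_Z"])
        vel = _cols(noisy_trial, site, ["VelInc_X", "VelInc_Y", "VelInc_Z"])
        assert np.array_equal(vel, acc / 100.0)

    @pytest.mark.parametrize("site", list(Site))
    def test_free_acc_plus_gravity_projection_is_acc(self, noisy_trial, site):
        ypr = _cols(noisy_trial, site, ["Yaw", "Pitch", "Roll"])
        R = euler_zyx_matrices(ypr[:, 0], ypr[:, 1], ypr[:, 2])
        grav_body = np.einsum("nji,j->ni", R, np.array([0.0, 0.0, -GRAVITY]))
        acc = _cols(noisy_trial, site, ["Acc_X", "Acc_Y", "Acc_Z"])
        free = _cols(noisy_trial, site, ["FreeAcc_X", "FreeAcc_Y", "FreeAcc_Z"])
        assert np.allclose(free + grav_body, acc, atol=1e-12)

    @pytest.mark.parametrize("site", list(Site))
    def test_orientation_increment_is_unit_quaternion(self, noisy_trial, site):
        q = _cols(noisy_trial, site,
                  ["OriInc_q0", "OriInc_q1", "OriInc_q2", "OriInc_q3"])
        assert np.abs(np.linalg.norm(q, axis=1) - 1.0).max() < 1e-9
        assert q[:, 0].min() > 0.9  # small per-sample rotations

    def test_quiet_trial_measures_pure_gravity_and_field(self, quiet_trial):
        acc = _cols(quiet_trial, Site.trunk, ["Acc_X", "Acc_Y", "Acc_Z"])
        mag = _cols(quiet_trial, Site.trunk, ["Mag_X", "Mag_Y", "Mag_Z"])
        assert np.allclose(acc, [0.0, 0.0, -GRAVITY], atol=1e-12)
        assert np.allclose(mag, B_EARTH, atol=1e-12)


class TestSurfaceStructure:
    def test_slope_pitch_baselines_are_antisymmetric(self):
        cfg = quiet_config()
        cfg.surface_effects[Surface.SlpU] = g.simulate.SurfaceEffect(
            pitch_deg=10.0, jitter_sd_deg=0.0)
        cfg.surface_effects[Surface.SlpD] = g.simulate.SurfaceEffect(
            pitch_deg=-10.0, jitter_sd_deg=0.0)
        rng = np.random.default_rng(0)
        profile = sample_profile(cfg, rng)
        up = simulate_trial(profile, Surface.SlpU, 3.0, rng, cfg)
        down = simulate_trial(profile, Surface.SlpD, 3.0, rng, cfg)
        p_up = _cols(up, Site.shankR, ["Pitch"]).mean()
        p_down = _cols(down, Site.shankR, ["Pitch"]).mean()
        assert p_up == pytest.approx(-p_down, abs=1e-9)
        assert p_up > 0

    def test_shank_gyro_spectrum_peaks_at_cadence(self):
        # zero jitter and noise: the rate-of-turn spectrum is a clean line
        cfg = quiet_config(osc_amp_deg=8.0, duration_mean_s=20.0)
        rng = np.random.default_rng(1)
        profile = sample_profile(cfg, rng)
        trial = simulate_trial(profile, Surface.FE, 20.0, rng, cfg)
        gyr_y = _cols(trial, Site.shankR, ["Gyr_Y"])[:, 0]
        n = len(gyr_y)
        spec = np.abs(np.fft.rfft(gyr_y - gyr_y.mean()))
        freqs = np.fft.rfftfreq(n, d=1.0 / 100.0)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - profile.cadence_hz) <= freqs[1]  # within one bin

    def test_rotation_matrices_match_scipy(self):
        rng = np.random.default_rng(5)
        ypr = rng.uniform(-60, 60, size=(50, 3))
        ours = euler_zyx_matrices(ypr[:, 0], ypr[:, 1], ypr[:, 2])
        ref = Rotation.from_euler("ZYX", ypr, degrees=True).as_matrix()
        assert np.allclose(ours, ref, atol=1e-12)


class TestCohort:
    def test_full_factorial_counts(self):
        cfg = quiet_config(n_participants=2, trials_per_condition=1)
        assert len(simulate_cohort(cfg)) == 18

    def test_default_design_is_participants_by_surfaces_by_trials(self):
        cfg = quiet_config(n_participants=3, trials_per_condition=2)
        ds = simulate_cohort(cfg)
        assert len(ds) == 3 * 9 * 2
        assert len(set(ds.keys)) == len(ds)

    def test_durations_respect_truncation_floor(self):
        cfg = quiet_config(duration_mean_s=2.5, duration_sd_s=2.0,
                           duration_min_s=2.0, n_participants=2,
                           trials_per_condition=2)
        ds = simulate_cohort(cfg)
        assert min(t.duration_s for t in ds) >= 2.0

    def test_same_seed_is_bitwise_identical(self):
        cfg = g.default_config(
            n_participants=2, trials_per_condition=1, duration_mean_s=3.0,
            duration_sd_s=0.5, duration_min_s=2.0, missing_sensor_trials=2,
            seed=9)
        d1, d2 = simulate_cohort(cfg), simulate_cohort(cfg)
        for t1, t2 in zip(d1, d2):
            assert t1.key == t2.key
            for site in t1.data:
                assert np.array_equal(t1.data[site], t2.data[site],
                                      equal_nan=True)

    def test_rejects_subsecond_duration(self):
        cfg = quiet_config()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="duration"):
            simulate_trial(sample_profile(cfg, rng), Surface.FE, 0.5, rng, cfg)


class TestInjectMissing:
    @pytest.fixture()
    def cohort(self):
        return simulate_cohort(quiet_config(n_participants=2,
                                            trials_per_condition=2))

    def test_exact_trial_count_goes_missing(self, cohort):
        rng = np.random.default_rng(0)
        out = inject_missing(cohort, Site.thighL, 14, rng)
        n_missing = sum(t.sensor_missing(Site.thighL) for t in out)
        assert n_missing == 14
        assert len(out) == len(cohort)  # trials kept, stream blanked

    def test_zero_is_identity(self, cohort):
        rng = np.random.default_rng(0)
        assert inject_missing(cohort, Site.thighL, 0, rng) is cohort

    def test_all_trials_boundary(self, cohort):
        rng = np.random.default_rng(0)
        out = inject_missing(cohort, Site.wrist, len(cohort), rng)
        assert all(t.sensor_missing(Site.wrist) for t in out)

    def test_too_many_trials_rejected(self, cohort):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            inject_missing(cohort, Site.wrist, len(cohort) + 1, rng)
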