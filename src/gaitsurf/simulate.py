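"""Synthetic multi-sensor IMU gait cohorts with surface-dependent structure.

The generator emulates the design of an outdoor gait study: a cohort of
participants each walking six trials on nine surface conditions while
wearing six inertial sensors (wrist, both thighs, both shanks, trunk)
sampled at 100 Hz, with 22 channels per sensor.

Per sensor site the kinematic model is a sensor orientation composed of a
baseline (participant heading; surface-specific pitch/roll shifts), a
cadence-locked harmonic oscillation whose amplitude scales with a per-site
gain (shanks > thighs > trunk >> wrist), and orientation jitter whose
spread scales with a per-surface roughness factor.  All 22 channels are
derived from that orientation and a cadence-locked body acceleration, so
the physical identities between channels (velocity increment = Acc/rate,
FreeAcc = Acc minus the gravity projection, unit orientation-increment
quaternions) hold exactly on every generated trial.

Surfaces differ by orientation baselines (slopes shift pitch, banks shift
roll, with opposite signs for up/down and left/right), cadence and
vertical-amplitude factors (stairs: slower cadence, larger amplitude), and
jitter level (grass and cobblestone are rough; flat-even is the low-noise
reference), making flat-even/grass/cobblestone the hardest triple to
separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CHANNEL_NAMES,
    N_CHANNELS_PER_SENSOR,
    GaitDataset,
    Site,
    Surface,
    Trial,
)

__all__ = [
    "SurfaceEffect",
    "SimulationConfig",
    "ParticipantProfile",
    "default_config",
    "separable_config",
    "planted_mag_config",
    "sample_profile",
    "simulate_trial",
    "simulate_cohort",
    "inject_missing",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2

#: Earth magnetic field direction in arbitrary units (world frame).
B_EARTH = np.array([0.33, 0.0, -0.44])


@dataclass(frozen=True)
class SurfaceEffect:
    """How one surface condition perturbs the gait kinematics.

    pitch_deg / roll_deg
        Orientation baseline shift (slopes tilt pitch, banks tilt roll).
    cadence_factor
        Multiplier on the participant's stride cadence (<1 on stairs).
    vertical_amp_factor
        Multiplier on the oscillation / body-acceleration amplitude
        (>1 on stairs and rough ground).
    jitter_sd_deg
        Standard deviation of white orientation jitter, degrees, before
        site scaling (rough surfaces are large; flat-even is the floor).
    mag_deviation_deg
        Optional yaw rotation of the reference magnetic-field vector for
        this surface.  Zero in the physical presets; used by the planted
        preset to make the magnetometer the only informative group.
    """

    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    cadence_factor: float = 1.0
    vertical_amp_factor: float = 1.0
    jitter_sd_deg: float = 0.5
    mag_deviation_deg: float = 0.0


def _default_surface_effects() -> dict[Surface, SurfaceEffect]:
    return {
        Surface.FE: SurfaceEffect(jitter_sd_deg=0.5),
        Surface.StrU: SurfaceEffect(pitch_deg=12.0, cadence_factor=0.70,
                                    vertical_amp_factor=1.8, jitter_sd_deg=0.8),
        Surface.StrD: SurfaceEffect(pitch_deg=-12.0, cadence_factor=0.70,
                                    vertical_amp_factor=1.8, jitter_sd_deg=0.8),
        Surface.SlpU: SurfaceEffect(pitch_deg=10.0, cadence_factor=0.95,
                                    vertical_amp_factor=1.1, jitter_sd_deg=0.7),
        Surface.SlpD: SurfaceEffect(pitch_deg=-10.0, cadence_factor=0.95,
                                    vertical_amp_factor=1.1, jitter_sd_deg=0.7),
        Surface.GR: SurfaceEffect(cadence_factor=0.92, vertical_amp_factor=1.25,
                                  jitter_sd_deg=1.5),
        Surface.BnkL: SurfaceEffect(roll_deg=8.0, cadence_factor=0.97,
                                    jitter_sd_deg=0.7),
        Surface.BnkR: SurfaceEffect(roll_deg=-8.0, cadence_factor=0.97,
                                    jitter_sd_deg=0.7),
        Surface.CS: SurfaceEffect(cadence_factor=0.90, vertical_amp_factor=1.4,
                                  jitter_sd_deg=2.5),
    }


def _default_site_gain() -> dict[Site, float]:
    # Surface signal strength by body site: lower limb >> wrist.
    return {
        Site.wrist: 0.15,
        Site.thighR: 0.60,
        Site.thighL: 0.60,
        Site.shankR: 1.00,
        Site.shankL: 1.00,
        Site.trunk: 0.35,
    }


def _default_noise_sd() -> dict[str, float]:
    # Additive white measurement noise per channel family.
    return {"Acc": 0.05, "Gyr": 0.02, "Mag": 0.01}


def _default_jitter_floor() -> dict[Site, float]:
    # Surface-independent orientation jitter (degrees).  The wrist floor is
    # large: involuntary upper-extremity movement is irregular regardless of
    # the surface, which is what makes wrist recordings poor surface probes.
    return {
        Site.wrist: 4.0,
        Site.thighR: 0.2,
        Site.thighL: 0.2,
        Site.shankR: 0.2,
        Site.shankL: 0.2,
        Site.trunk: 0.3,
    }


@dataclass
class SimulationConfig:
    """Cohort design and effect sizes for the synthetic study.

    Defaults mirror the emulated study design: 30 participants, 6 trials
    per surface condition, trial durations ~N(16.4, 4.2^2) s truncated at
    6 s, 100 Hz sampling, and 14 trials with a fully missing left-thigh
    recording.
    """

    n_participants: int = 30
    trials_per_condition: int = 6
    duration_mean_s: float = 16.4
    duration_sd_s: float = 4.2
    duration_min_s: float = 6.0
    sample_rate: float = 100.0
    cadence_mean_hz: float = 1.8
    cadence_sd: float = 0.15
    surface_effects: dict[Surface, SurfaceEffect] = field(
        default_factory=_default_surface_effects
    )
    site_gain: dict[Site, float] = field(default_factory=_default_site_gain)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    site_jitter_floor_deg: dict[Site, float] = field(
        default_factory=_default_jitter_floor)
    #: Base orientation oscillation amplitude (degrees) and body acceleration
    #: amplitude (m/s^2) at site gain 1.0, before surface factors.
    osc_amp_deg: float = 8.0
    motion_amp: float = 2.0
    #: Spread of participant baseline headings (uniform [0, range) degrees).
    #: The planted preset sets 0 so magnetometer surface coding is not
    #: confounded with per-participant heading.
    heading_range_deg: float = 360.0
    missing_sensor_trials: int = 14
    missing_sensor: Site = Site.thighL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min_s <= 0 or self.duration_mean_s <= 0:
            raise ValueError("durations must be positive")
        if any(g <= 0 for g in self.site_gain.values()):
            raise ValueError("site gains must be positive")
        if self.trials_per_condition < 1 or self.n_participants < 1:
            raise ValueError("cohort counts must be >= 1")


def default_config(**overrides) -> SimulationConfig:
    """The study-design default cohort."""
    return SimulationConfig(**overrides)


def separable_config(**overrides) -> SimulationConfig:
    """Strong surface effects and low noise: a desk-scale, separable cohort.

    Effect sizes are doubled where surfaces would otherwise overlap and
    measurement noise is reduced, so a small network separates the nine
    classes from short windows within a few epochs.
    """
    effects = {
        Surface.FE: SurfaceEffect(jitter_sd_deg=0.3),
        Surface.StrU: SurfaceEffect(pitch_deg=16.0, cadence_factor=0.65,
                                    vertical_amp_factor=2.0, jitter_sd_deg=0.4),
        Surface.StrD: SurfaceEffect(pitch_deg=-16.0, cadence_factor=0.65,
                                    vertical_amp_factor=2.0, jitter_sd_deg=0.4),
        Surface.SlpU: SurfaceEffect(pitch_deg=12.0, cadence_factor=0.95,
                                    vertical_amp_factor=1.1, jitter_sd_deg=0.35),
        Surface.SlpD: SurfaceEffect(pitch_deg=-12.0, cadence_factor=0.95,
                                    vertical_amp_factor=1.1, jitter_sd_deg=0.35),
        Surface.GR: SurfaceEffect(cadence_factor=0.85, vertical_amp_factor=1.5,
                                  jitter_sd_deg=1.8),
        Surface.BnkL: SurfaceEffect(roll_deg=12.0, jitter_sd_deg=0.35),
        Surface.BnkR: SurfaceEffect(roll_deg=-12.0, jitter_sd_deg=0.35),
        Surface.CS: SurfaceEffect(cadence_factor=0.75, vertical_amp_factor=1.8,
                                  jitter_sd_deg=3.5),
    }
    cfg = SimulationConfig(
        surface_effects=effects,
        noise_sd={"Acc": 0.02, "Gyr": 0.01, "Mag": 0.005},
        missing_sensor_trials=0,
        **overrides,
    )
    return cfg


def planted_mag_config(**overrides) -> SimulationConfig:
    """A cohort where only the magnetometer group carries surface signal.

    All surfaces share identical kinematics (baselines, cadence, amplitude,
    jitter), but each surface rotates the reference magnetic-field vector by
    a distinct yaw angle.  Every non-Mag channel is therefore surface-blind
    by construction.
    """
    effects = {
        s: SurfaceEffect(jitter_sd_deg=0.5, mag_deviation_deg=40.0 * s.value)
        for s in Surface
    }
    return SimulationConfig(
        surface_effects=effects,
        noise_sd={"Acc": 0.02, "Gyr": 0.01, "Mag": 0.005},
        missing_sensor_trials=0,
        heading_range_deg=0.0,
        **overrides,
    )


@dataclass
class ParticipantProfile:
    """Per-participant gait idiosyncrasies."""

    cadence_hz: float
    amp_scale: dict[Site, float]
    baseline_yaw_deg: float
    arm_phase: float
    arm_amp_deg: float

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValueError("cadence must be positive")


def sample_profile(config: SimulationConfig, rng: np.random.Generator) -> ParticipantProfile:
    cadence = max(0.5, rng.normal(config.cadence_mean_hz, config.cadence_sd))
    amp = {site: float(rng.lognormal(0.0, 0.12)) for site in Site}
    return ParticipantProfile(
        cadence_hz=float(cadence),
        amp_scale=amp,
        baseline_yaw_deg=float(rng.uniform(0.0, config.heading_range_deg))
        if config.heading_range_deg > 0 else 0.0,
        arm_phase=float(rng.uniform(0.0, 2 * np.pi)),
        arm_amp_deg=float(rng.uniform(4.0, 14.0)),
    )


def euler_zyx_matrices(yaw_deg: np.ndarray, pitch_deg: np.ndarray,
                       roll_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices for intrinsic Z-Y-X (yaw-pitch-roll) Euler angles.

    Returns [n, 3, 3] matrices R such that R maps body-frame vectors to the
    world frame; world vectors are measured in the body frame via R^T v.
    """
    y, p, r = (np.deg2rad(np.asarray(a, dtype=float)) for a in
               (yaw_deg, pitch_deg, roll_deg))
    cy, sy, cp, sp, cr, sr = np.cos(y), np.sin(y), np.cos(p), np.sin(p), np.cos(r), np.sin(r)
    R = np.empty(y.shape + (3, 3))
    R[..., 0, 0] = cy * cp
    R[..., 0, 1] = cy * sp * sr - sy * cr
    R[..., 0, 2] = cy * sp * cr + sy * sr
    R[..., 1, 0] = sy * cp
    R[..., 1, 1] = sy * sp * sr + cy * cr
    R[..., 1, 2] = sy * sp * cr - cy * sr
    R[..., 2, 0] = -sp
    R[..., 2, 1] = cp * sr
    R[..., 2, 2] = cp * cr
    return R


def _measure_world_vector(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Express a world-frame vector in the body frame: R^T v, per sample."""
    return np.einsum("nji,j->ni", R, v)


def simulate_trial(
    profile: ParticipantProfile,
    surface: Surface,
    duration_s: float,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
    participant_id: int = 1,
    trial_index: int = 1,
) -> Trial:
    """Simulate one walking trial with all six sensors.

    Every channel is derived from a single per-site orientation trajectory
    and cadence-locked body acceleration, so inter-channel physical
    identities hold exactly (see module docstring).
    """
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    config = config or SimulationConfig()
    eff = config.surface_effects[Surface(surface)]
    fs = config.sample_rate
    n = int(math.floor(duration_s * fs + 1e-9))
    t = np.arange(n) / fs
    cadence = profile.cadence_hz * eff.cadence_factor
    omega = 2 * np.pi * cadence
    noise = config.noise_sd

    b_earth = B_EARTH
    if eff.mag_deviation_deg:
        Rb = euler_zyx_matrices(np.array(eff.mag_deviation_deg), np.array(0.0),
                                np.array(0.0))
        b_earth = Rb @ B_EARTH

    data: dict[Site, np.ndarray] = {}
    for site in Site:
        gain = config.site_gain[site] * profile.amp_scale[site]
        A = config.osc_amp_deg * gain * eff.vertical_amp_factor
        # Per-axis phases fixed per site so left/right sensors differ.
        ph = 0.9 * site.value
        # Cadence-locked oscillation with a second harmonic, plus an
        # idiosyncratic arm swing at the wrist only.
        yaw_osc = 0.4 * A * np.sin(omega * t + ph)
        pitch_osc = A * np.sin(omega * t + ph + 0.5) + 0.3 * A * np.sin(
            2 * omega * t + 2 * ph)
        roll_osc = 0.5 * A * np.sin(omega * t + ph + 1.1)
        arm_amp = 0.0
        if site == Site.wrist:
            # Involuntary arm swing varies trial to trial (amplitude and
            # phase), so it carries no stable surface information.
            arm_amp = profile.arm_amp_deg * rng.lognormal(0.0, 0.4)
            arm_phase = rng.uniform(0.0, 2 * np.pi)
            arm = arm_amp * np.sin(omega * t + arm_phase)
            pitch_osc = pitch_osc + arm
        # Surface baselines and surface-roughness jitter scale with the
        # site gain so the surface signal concentrates in the lower limbs;
        # the surface-independent floor dominates at the wrist.
        sgain = config.site_gain[site]
        jitter_sd = (eff.jitter_sd_deg * sgain
                     + config.site_jitter_floor_deg.get(site, 0.0))
        jit = rng.normal(0.0, jitter_sd, size=(3, n)) if jitter_sd > 0 else np.zeros((3, n))
        yaw = profile.baseline_yaw_deg + yaw_osc + jit[0]
        pitch = eff.pitch_deg * sgain + pitch_osc + jit[1]
        roll = eff.roll_deg * sgain + roll_osc + jit[2]

        # Rate of turn: analytic time-derivative of the oscillatory
        # orientation component (deg/s -> rad/s), plus white noise.  Euler
        # rates stand in for body rates, adequate at these amplitudes.
        dyaw = 0.4 * A * omega * np.cos(omega * t + ph)
        dpitch = A * omega * np.cos(omega * t + ph + 0.5) + 0.6 * A * omega * np.cos(
            2 * omega * t + 2 * ph)
        if site == Site.wrist:
            dpitch = dpitch + arm_amp * omega * np.cos(
                omega * t + arm_phase)
        droll = 0.5 * A * omega * np.cos(omega * t + ph + 1.1)
        gyr = np.deg2rad(np.stack([droll, dpitch, dyaw], axis=1))
        gyr = gyr + rng.normal(0.0, noise.get("Gyr", 0.0), size=gyr.shape)

        R = euler_zyx_matrices(yaw, pitch, roll)
        grav_body = _measure_world_vector(R, np.array([0.0, 0.0, -GRAVITY]))

        # Cadence-locked body acceleration, vertical-dominant.
        M = config.motion_amp * gain * eff.vertical_amp_factor
        motion = np.stack(
            [
                0.3 * M * np.sin(omega * t + ph + 0.7),
                0.3 * M * np.sin(omega * t + ph + 1.9),
                M * np.sin(2 * omega * t + ph)
                + 0.4 * M * np.sin(omega * t + ph + 0.2),
            ],
            axis=1,
        )
        acc = (grav_body + motion
               + rng.normal(0.0, noise.get("Acc", 0.0), size=(n, 3)))
        free_acc = acc - grav_body  # exact by construction
        mag = (_measure_world_vector(R, b_earth)
               + rng.normal(0.0, noise.get("Mag", 0.0), size=(n, 3)))
        vel_inc = acc / fs  # exact by construction

        # Orientation increment: unit quaternion of the small rotation
        # gyr * dt, q0 ~ 1.
        rotvec = gyr / fs
        angle = np.linalg.norm(rotvec, axis=1)
        half = angle / 2.0
        q0 = np.cos(half)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(angle > 0, np.sin(half) / np.where(angle > 0, angle, 1.0), 0.5)
        qvec = rotvec * s[:, None]
        ori_inc = np.column_stack([q0, qvec])

        ypr = np.stack([yaw, pitch, roll], axis=1)
        mat = np.concatenate([acc, free_acc, gyr, mag, vel_inc, ori_inc, ypr],
                             axis=1)
        assert mat.shape == (n, N_CHANNELS_PER_SENSOR)
        data[site] = mat

    return Trial(
        participant_id=participant_id,
        surface=Surface(surface),
        trial_index=trial_index,
        data=data,
        sample_rate=fs,
    )


def simulate_cohort(config: SimulationConfig | None = None) -> GaitDataset:
    """Simulate the full factorial cohort: participants x surfaces x trials.

    Trial durations are drawn from a normal distribution truncated below at
    ``duration_min_s``.  The same seed reproduces the cohort bitwise.  If
    ``missing_sensor_trials`` > 0, that many randomly chosen trials have the
    configured sensor's recording replaced by NaNs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    trials: list[Trial] = []
    for pid in range(1, config.n_participants + 1):
        profile = sample_profile(config, rng)
        for surface in Surface:
            for idx in range(1, config.trials_per_condition + 1):
                dur = 0.0
                while dur < config.duration_min_s:
                    dur = rng.normal(config.duration_mean_s, config.duration_sd_s)
                trials.append(
                    simulate_trial(profile, surface, dur, rng, config,
                                   participant_id=pid, trial_index=idx)
                )
    dataset = GaitDataset(trials=trials, provenance="synthetic")
    if config.missing_sensor_trials > 0:
        dataset = inject_missing(dataset, config.missing_sensor,
                                 config.missing_sensor_trials, rng)
    return dataset


def inject_missing(
    dataset: GaitDataset,
    sensor: Site,
    n_trials: int,
    rng: np.random.Generator,
) -> GaitDataset:
    """Replace the named sensor's recording with NaNs in n random trials."""
    sensor = Site(sensor)
    if n_trials < 0 or n_trials > len(dataset):
        raise ValueError(f"n_trials must be in [0, {len(dataset)}]")
    if n_trials == 0:
        return dataset
    chosen = set(rng.choice(len(dataset), size=n_trials, replace=False).tolist())
    new_trials = []
    for i, trial in enumerate(dataset):
        if i in chosen and sensor in trial.data:
            data = dict(trial.data)
            data[sensor] = np.full_like(data[sensor], np.nan)
            trial = replace(trial, data=data)
        new_trials.append(trial)
    return GaitDataset(trials=new_trials, provenance=dataset.provenance)
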