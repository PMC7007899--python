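"""Closed-loop inverted-pendulum sway simulator.

The body is a single inverted pendulum rotating about the ankle,
stabilized by a delayed PID controller acting on a weighted mixture of two
sensory error signals: a proprioceptive channel referencing the body to the
platform (weight ``w_prop``) and a graviceptive channel referencing it to
gravitational vertical (weight ``1 - w_prop``).  Linearized about upright:

    J theta'' = m g h theta + T(t)
    T(t)      = [Kp e + Kd e' + Ki \int e](t - delay) + torque noise
    e(t)      = w_prop * u(t) + r - theta(t)

with u the platform tilt and r the lean set-point.  The closed-loop
stimulus response is

    H(f) = w_prop P C / (1 + P C),     s = i 2 pi f,
    P(s) = 1 / (J s^2 - m g h),        C(s) = (Kp + Kd s + Ki/s) e^{-delay s},

which :func:`analytic_frf` evaluates in closed form and the fixed-step
time-domain integrator reproduces; the analytic curve serves as an exact
oracle for the whole estimation pipeline.

Recordings carry, besides the true center-of-mass (COM) angle, the
quantities an actual posturography rig measures: hip and shoulder
anterior-posterior translations from a two-segment geometry (with a small,
slow hip-bend oscillation so the two markers are not collinear) and the
center of pressure computed from the ankle torque balance,
``cop = h sin(theta) - J theta'' / (m g)``, which tracks the COM projection
exactly in quasi-static motion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.linalg import expm
from scipy.signal import lfilter

from .stimuli import StimulusSequence

__all__ = [
    "BalanceModelParams",
    "SegmentGeometry",
    "SwayRecording",
    "LearningCohortConfig",
    "UnstableLoopError",
    "SimulatedFallError",
    "analytic_frf",
    "simulate_sway",
    "simulate_calibration_recording",
    "simulate_learning_cohort",
    "DEFAULT_GEOMETRY",
]

G = 9.81  # m/s^2


class UnstableLoopError(ValueError):
    """Raised when the closed loop is unstable for the given parameters."""


class SimulatedFallError(RuntimeError):
    """Raised when the simulated COM angle exceeds the fall threshold."""


@dataclass(frozen=True)
class SegmentGeometry:
    """Two-segment (legs + head-arms-trunk) marker geometry.

    Segment constants follow standard anthropometric tables: leg length
    (ankle to hip) 0.530 x body height, hip-to-shoulder 0.288 x body height,
    leg mass fraction 0.32 with COM at 0.55 of leg length, HAT mass fraction
    0.68 with COM at 0.543 of trunk length above the hip.  These combine to a
    whole-body COM height of 0.56 x body height.
    """

    body_height: float = 1.73
    leg_length_frac: float = 0.530
    trunk_length_frac: float = 0.288
    leg_mass_frac: float = 0.32
    leg_com_frac: float = 0.55
    trunk_com_frac: float = 0.543

    @property
    def leg_length(self) -> float:
        return self.leg_length_frac * self.body_height

    @property
    def trunk_length(self) -> float:
        return self.trunk_length_frac * self.body_height

    @property
    def a_leg(self) -> float:
        """Leg-angle lever of the whole-body COM (m)."""
        return (
            self.leg_mass_frac * self.leg_com_frac * self.leg_length
            + (1 - self.leg_mass_frac) * self.leg_length
        )

    @property
    def b_trunk(self) -> float:
        """Hip-bend lever of the whole-body COM (m)."""
        return (1 - self.leg_mass_frac) * self.trunk_com_frac * self.trunk_length

    @property
    def com_height(self) -> float:
        return self.a_leg + self.b_trunk

    @property
    def truth_coefficients(self) -> tuple[float, float]:
        """(coef_hip, coef_shoulder) of the exact linear map from marker
        translations to COM translation."""
        ch = self.a_leg / self.leg_length - self.b_trunk / self.trunk_length
        cs = self.b_trunk / self.trunk_length
        return ch, cs


DEFAULT_GEOMETRY = SegmentGeometry()


@dataclass(frozen=True)
class BalanceModelParams:
    """Plant and controller parameters of the balance model.

    Torque units are N*m per radian of error (Kp), per rad/s (Kd) and per
    rad*s (Ki).  ``w_prop`` is the proprioceptive weight in [0, 1]; the
    graviceptive weight is ``1 - w_prop``.  ``noise_sd`` is the stationary
    standard deviation (N*m) of the low-pass-filtered torque noise and
    ``noise_tau`` its filter time constant.  Defaults describe a 66.8-kg,
    1.73-m subject (COM height 0.56 x height, rod-like inertia 4/3 m h^2)
    and were tuned once so the closed-loop gain peaks between 0.1 and 0.3 Hz
    at a moderate resonance, the qualitative shape seen in tilt
    posturography; they are simulator conventions, not fitted values.
    """

    body_mass: float = 66.8
    com_height: float = DEFAULT_GEOMETRY.com_height
    inertia: float | None = None
    Kp: float = 850.0
    Kd: float = 280.0
    Ki: float = 10.0
    delay: float = 0.15
    w_prop: float = 0.4
    noise_sd: float = 0.0
    noise_tau: float = 1.0
    lean_setpoint: float = 0.0  # deg, toes-up positive
    cop_noise_sd: float = 0.0  # m, white sensor noise on the COP channel

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_prop <= 1.0:
            raise ValueError("w_prop must be in [0, 1]")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.inertia is None:
            object.__setattr__(
                self, "inertia", (4.0 / 3.0) * self.body_mass * self.com_height**2
            )

    @property
    def mgh(self) -> float:
        return self.body_mass * G * self.com_height


@dataclass
class SwayRecording:
    """Synchronized traces for one trial of one subject.

    Angles in degrees (toes-up positive), translations in meters.
    ``com_angle`` is the simulator's truth channel and is absent (None) for
    recordings read from measurement files without it.
    """

    time: np.ndarray
    platform_tilt: np.ndarray
    hip_x: np.ndarray
    shoulder_x: np.ndarray
    cop_x: np.ndarray
    sample_rate: float
    com_angle: np.ndarray | None = None
    subject_id: str = "sim"
    trial_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("platform_tilt", "hip_x", "shoulder_x", "cop_x"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length differs from time")
        if self.com_angle is not None and len(self.com_angle) != n:
            raise ValueError("com_angle length differs from time")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.time) / self.sample_rate


def _check_stable(params: BalanceModelParams) -> None:
    """Verify closed-loop stability by a short noise-free impulse simulation.

    The loop is released from a 1-degree COM offset with zero stimulus; the
    response envelope must decay.
    """
    try:
        rec = _integrate(
            u=np.zeros(1),
            params=replace(params, noise_sd=0.0, cop_noise_sd=0.0, lean_setpoint=0.0),
            duration=12.0,
            sample_rate=100.0,
            substeps=5,
            theta0_deg=1.0,
            seed=0,
            check_stability=False,
            fall_threshold_deg=60.0,
        )
    except SimulatedFallError as err:
        raise UnstableLoopError(
            "closed loop is unstable: impulse response diverges "
            f"(Kp={params.Kp}, Kd={params.Kd}, Ki={params.Ki}, "
            f"delay={params.delay}): {err}"
        ) from None
    theta = rec[0]
    early = np.max(np.abs(theta[: len(theta) // 3]))
    late = np.max(np.abs(theta[-len(theta) // 3 :]))
    if not np.isfinite(late) or late > 0.8 * early:
        raise UnstableLoopError(
            "closed loop is unstable: impulse response envelope grows from "
            f"{early:.3g} to {late:.3g} deg over 12 s "
            f"(Kp={params.Kp}, Kd={params.Kd}, Ki={params.Ki}, "
            f"delay={params.delay})"
        )


def analytic_frf(params: BalanceModelParams, freqs: np.ndarray) -> np.ndarray:
    """Closed-form stimulus -> COM frequency response H(f).

    ``H(f) = w_prop P C / (1 + P C)`` with ``P = 1/(J s^2 - m g h)`` and
    ``C = (Kp + Kd s + Ki/s) exp(-delay s)`` at ``s = i 2 pi f``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("freqs must be strictly positive")
    _check_stable(params)
    s = 2j * np.pi * freqs
    P = 1.0 / (params.inertia * s**2 - params.mgh)
    C = (params.Kp + params.Kd * s + params.Ki / s) * np.exp(-params.delay * s)
    return params.w_prop * P * C / (1.0 + P * C)


@njit(cache=True)
def _loop(
    u_rad,
    du_rad,
    noise,
    ad00,
    ad01,
    ad10,
    ad11,
    bd0,
    bd1,
    Kp,
    Kd,
    Ki,
    w,
    r_rad,
    dt,
    delay_steps,
    theta0,
    integ0,
    fall_rad,
):  # pragma: no cover - exercised via simulate_sway
    n = u_rad.shape[0]
    theta = np.empty(n)
    thetadd_t = np.empty(n)
    buf_len = max(delay_steps, 1)
    buf = np.empty(buf_len)
    t_cmd0 = Kp * (w * u_rad[0] + r_rad - theta0) + Ki * integ0
    for i in range(buf_len):
        buf[i] = t_cmd0
    x0 = theta0
    x1 = 0.0
    integ = integ0
    e_prev = w * u_rad[0] + r_rad - x0
    head = 0
    for k in range(n):
        e = w * u_rad[k] + r_rad - x0
        de = w * du_rad[k] - x1
        integ += 0.5 * (e + e_prev) * dt
        e_prev = e
        t_cmd = Kp * e + Kd * de + Ki * integ
        # read-then-write on a ring of length delay_steps => exact
        # integer-substep delay; zero delay applies the command directly
        if delay_steps == 0:
            t_app = t_cmd + noise[k]
        else:
            t_app = buf[head] + noise[k]
            buf[head] = t_cmd
            head += 1
            if head == buf_len:
                head = 0
        theta[k] = x0
        thetadd_t[k] = t_app  # store torque; acceleration formed outside
        nx0 = ad00 * x0 + ad01 * x1 + bd0 * t_app
        nx1 = ad10 * x0 + ad11 * x1 + bd1 * t_app
        x0 = nx0
        x1 = nx1
        if abs(x0) > fall_rad:
            theta[k + 1 :] = np.nan
            thetadd_t[k + 1 :] = np.nan
            return theta, thetadd_t, k
    return theta, thetadd_t, -1


def _integrate(
    u: np.ndarray,
    params: BalanceModelParams,
    duration: float,
    sample_rate: float,
    substeps: int,
    theta0_deg: float | None,
    seed,
    check_stability: bool,
    fall_threshold_deg: float = 30.0,
    start_at_equilibrium: bool = True,
):
    """Run the fixed-step closed loop; returns (theta_deg, thetadd, u_deg)
    decimated to ``sample_rate``.

    ``u`` is the platform tilt in degrees sampled at ``sample_rate`` (a
    single value is held constant).  Internally the plant is discretized
    exactly (matrix exponential) at ``sample_rate * substeps`` Hz with the
    torque held constant over each substep and the delay as an
    integer-substep ring buffer.
    """
    if check_stability:
        _check_stable(params)
    n_out = int(round(duration * sample_rate))
    dt = 1.0 / (sample_rate * substeps)
    n_int = n_out * substeps

    u = np.asarray(u, dtype=float)
    if u.size == 1:
        u_s = np.full(n_out + 1, u.item())
    else:
        if u.size < n_out:
            raise ValueError("stimulus shorter than requested duration")
        u_s = np.concatenate([u[:n_out], u[n_out - 1 : n_out]])
    # linear interpolation to the internal rate; derivative piecewise constant
    du_samp = np.diff(u_s) * sample_rate
    u_int = np.repeat(u_s[:-1], substeps) + np.repeat(du_samp, substeps) * (
        np.tile(np.arange(substeps), n_out) * dt
    )
    du_int = np.repeat(du_samp, substeps)
    u_rad = np.deg2rad(u_int)
    du_rad = np.deg2rad(du_int)

    J, mgh = params.inertia, params.mgh
    A = np.array([[0.0, 1.0], [mgh / J, 0.0]])
    M = np.zeros((3, 3))
    M[:2, :2] = A
    M[:2, 2] = [0.0, 1.0 / J]
    E = expm(M * dt)
    Ad, Bd = E[:2, :2], E[:2, 2]

    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        alpha = np.exp(-dt / params.noise_tau)
        white = rng.standard_normal(n_int)
        noise = lfilter([np.sqrt(1 - alpha**2)], [1.0, -alpha], white) * params.noise_sd
    else:
        noise = np.zeros(n_int)

    r_rad = np.deg2rad(params.lean_setpoint)
    if theta0_deg is None:
        theta0 = r_rad + params.w_prop * u_rad[0] if start_at_equilibrium else 0.0
    else:
        theta0 = np.deg2rad(theta0_deg)
    # integral state that holds the equilibrium torque -mgh*theta0 at e = 0
    integ0 = -mgh * theta0 / params.Ki if params.Ki > 0 and theta0_deg is None else 0.0

    delay_steps = int(round(params.delay / dt))
    theta_rad, torque, fell = _loop(
        u_rad,
        du_rad,
        noise,
        Ad[0, 0],
        Ad[0, 1],
        Ad[1, 0],
        Ad[1, 1],
        Bd[0],
        Bd[1],
        params.Kp,
        params.Kd,
        params.Ki,
        params.w_prop,
        r_rad,
        dt,
        delay_steps,
        theta0,
        integ0,
        np.deg2rad(fall_threshold_deg),
    )
    if fell >= 0:
        raise SimulatedFallError(
            f"simulated fall: |COM angle| exceeded {fall_threshold_deg} deg "
            f"at t = {fell * dt:.2f} s"
        )
    thetadd = (mgh * theta_rad + torque) / J
    sl = slice(0, n_int, substeps)
    return np.rad2deg(theta_rad[sl]), thetadd[sl], u_int[sl], rng


def _marker_channels(
    theta_deg: np.ndarray,
    sample_rate: float,
    geometry: SegmentGeometry,
    rng: np.random.Generator,
    hip_wobble_deg: float,
    hip_wobble_hz: float,
):
    """Derive hip/shoulder marker translations from the COM angle.

    A small, slow hip-bend oscillation delta(t) is superposed; the leg angle
    is solved exactly so the two-segment COM reproduces the pendulum COM:
    a sin(th_l) + b sin(th_l + delta) = h sin(theta).
    """
    n = len(theta_deg)
    t = np.arange(n) / sample_rate
    phase = rng.uniform(0, 2 * np.pi)
    delta = np.deg2rad(hip_wobble_deg) * np.sin(2 * np.pi * hip_wobble_hz * t + phase)
    a, b = geometry.a_leg, geometry.b_trunk
    h = geometry.com_height
    theta = np.deg2rad(theta_deg)
    R = np.sqrt((a + b * np.cos(delta)) ** 2 + (b * np.sin(delta)) ** 2)
    phi = np.arctan2(b * np.sin(delta), a + b * np.cos(delta))
    theta_leg = np.arcsin(np.clip(h * np.sin(theta) / R, -1, 1)) - phi
    hip_x = geometry.leg_length * np.sin(theta_leg)
    shoulder_x = hip_x + geometry.trunk_length * np.sin(theta_leg + delta)
    return hip_x, shoulder_x


def simulate_sway(
    stimulus: StimulusSequence,
    params: BalanceModelParams,
    seed=None,
    *,
    substeps: int = 10,
    geometry: SegmentGeometry = DEFAULT_GEOMETRY,
    hip_wobble_deg: float = 0.2,
    hip_wobble_hz: float = 0.04,
    subject_id: str = "sim",
    trial_label: str | None = None,
    theta0_deg: float | None = None,
) -> SwayRecording:
    """Simulate one trial of one subject responding to ``stimulus``.

    Deterministic given ``seed``.  The loop starts at the equilibrium lean
    for the initial stimulus value (no onset transient beyond the stimulus's
    own dynamics) unless ``theta0_deg`` overrides the initial angle.
    """
    fs = stimulus.sample_rate
    theta_deg, thetadd, u_deg, rng = _integrate(
        stimulus.samples,
        params,
        stimulus.duration,
        fs,
        substeps,
        theta0_deg,
        seed,
        check_stability=False,
    )
    h = params.com_height
    cop = h * np.sin(np.deg2rad(theta_deg)) - params.inertia * thetadd / (
        params.body_mass * G
    )
    if params.cop_noise_sd > 0:
        cop = cop + rng.normal(0.0, params.cop_noise_sd, len(cop))
    hip_x, shoulder_x = _marker_channels(
        theta_deg, fs, geometry, rng, hip_wobble_deg, hip_wobble_hz
    )
    return SwayRecording(
        time=np.arange(len(theta_deg)) / fs,
        platform_tilt=u_deg,
        hip_x=hip_x,
        shoulder_x=shoulder_x,
        cop_x=cop,
        sample_rate=fs,
        com_angle=theta_deg,
        subject_id=subject_id,
        trial_label=trial_label or stimulus.label,
    )


def simulate_calibration_recording(
    geometry: SegmentGeometry = DEFAULT_GEOMETRY,
    duration: float = 120.0,
    sample_rate: float = 100.0,
    seed=None,
    cop_noise_sd: float = 0.0,
    ankle_amp_deg: float = 1.5,
    hip_amp_deg: float = 1.0,
    subject_id: str = "sim",
) -> SwayRecording:
    """Emulate the quasi-static calibration routine on the static platform.

    The subject performs slow ankle (two incommensurate sub-0.05-Hz sines)
    and hip-bend movements; the COP equals the COM projection exactly (plus
    optional white sensor noise), which is the premise the COP-regression
    calibration relies on.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    theta_leg = np.deg2rad(ankle_amp_deg) * (
        np.sin(2 * np.pi * 0.020 * t + rng.uniform(0, 2 * np.pi))
        + 0.6 * np.sin(2 * np.pi * 0.037 * t + rng.uniform(0, 2 * np.pi))
    )
    delta = np.deg2rad(hip_amp_deg) * np.sin(
        2 * np.pi * 0.051 * t + rng.uniform(0, 2 * np.pi)
    )
    hip_x = geometry.leg_length * np.sin(theta_leg)
    shoulder_x = hip_x + geometry.trunk_length * np.sin(theta_leg + delta)
    com_x = geometry.a_leg * np.sin(theta_leg) + geometry.b_trunk * np.sin(
        theta_leg + delta
    )
    cop = com_x.copy()
    if cop_noise_sd > 0:
        cop += rng.normal(0.0, cop_noise_sd, n)
    com_angle = np.rad2deg(np.arcsin(com_x / geometry.com_height))
    return SwayRecording(
        time=t,
        platform_tilt=np.zeros(n),
        hip_x=hip_x,
        shoulder_x=shoulder_x,
        cop_x=cop,
        sample_rate=sample_rate,
        com_angle=com_angle,
        subject_id=subject_id,
        trial_label="calibration",
    )


@dataclass
class LearningCohortConfig:
    """Cohort and trial-to-trial drift configuration for the learning phase.

    Defaults emulate the study conditions: 19 subjects, 75 trials, the lean
    set-point decaying exponentially from 3.3 to 2.4 deg across trials and
    the proprioceptive weight decaying so the stimulus-evoked sway power
    drops by 33% (amplitude ratio sqrt(0.67)), both with time constant 25
    trials.  Noise-driven (non-stimulus) sway is held fixed across trials.
    Between-subject dispersion perturbs the set-point, weight and stiffness.
    All randomness derives from ``seed``.
    """

    n_subjects: int = 19
    n_trials: int = 75
    drift_enabled: bool = True
    setpoint_start: float = 3.3  # deg
    setpoint_end: float = 2.4  # deg
    wprop_end_ratio: float = float(np.sqrt(0.67))
    drift_tau_trials: float = 25.0
    setpoint_subject_sd: float = 0.4  # deg
    wprop_subject_sd: float = 0.04
    kp_subject_frac_sd: float = 0.06
    noise_sd: float = 1.5  # N*m
    cop_noise_sd: float = 0.0005  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")


def _drift(start: float, end: float, trial: int, tau: float) -> float:
    return end + (start - end) * np.exp(-trial / tau)


def simulate_learning_cohort(
    cfg: LearningCohortConfig,
    stimulus: StimulusSequence,
    base_params: BalanceModelParams | None = None,
    substeps: int = 10,
) -> list[SwayRecording]:
    """Simulate ``n_subjects`` x ``n_trials`` learning-trial recordings.

    With drift enabled, each subject's lean set-point and proprioceptive
    weight decay exponentially across trials toward the configured ends, so
    downstream trend fits have known ground-truth directions; with drift
    disabled every trial is statistically identical.
    """
    if base_params is None:
        base_params = BalanceModelParams(
            noise_sd=cfg.noise_sd, cop_noise_sd=cfg.cop_noise_sd
        )
    _check_stable(base_params)
    ss = np.random.SeedSequence(cfg.seed)
    subject_seeds = ss.spawn(cfg.n_subjects)
    recordings: list[SwayRecording] = []
    for i, sseed in enumerate(subject_seeds):
        srng = np.random.default_rng(sseed)
        sp0 = cfg.setpoint_start + srng.normal(0, cfg.setpoint_subject_sd)
        sp1 = cfg.setpoint_end + srng.normal(0, cfg.setpoint_subject_sd)
        w0 = np.clip(base_params.w_prop + srng.normal(0, cfg.wprop_subject_sd), 0.05, 0.95)
        w1 = w0 * cfg.wprop_end_ratio
        kp = base_params.Kp * (1 + srng.normal(0, cfg.kp_subject_frac_sd))
        trial_seeds = sseed.spawn(cfg.n_trials)
        for t in range(cfg.n_trials):
            if cfg.drift_enabled:
                sp = _drift(sp0, sp1, t, cfg.drift_tau_trials)
                w = _drift(w0, w1, t, cfg.drift_tau_trials)
            else:
                sp, w = sp0, w0
            p = replace(
                base_params,
                Kp=kp,
                lean_setpoint=sp,
                w_prop=float(w),
                noise_sd=cfg.noise_sd,
                cop_noise_sd=cfg.cop_noise_sd,
            )
            recordings.append(
                simulate_sway(
                    stimulus,
                    p,
                    seed=trial_seeds[t],
                    substeps=substeps,
                    subject_id=f"S{i:02d}",
                    trial_label=f"learn{t:03d}",
                )
            )
    return recordings
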