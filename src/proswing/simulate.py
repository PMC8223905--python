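"""Synthetic two-limb sagittal-plane gait with a damped-pendulum prosthetic knee.

The generator emulates a transfemoral prosthesis user walking at steady
state.  The sound limb and all stance phases are prescribed (smooth
periodic kinematics); the prosthetic swing knee is the only simulated
dynamic element: a composite shank+foot pendulum about the moving knee
pivot, with a viscous flexion damper engaged through a one-way clutch
(resistive torque ``-c*db/dt`` only while flexing), constant Coulomb
friction, and a compliant extension bumper at full extension.

Marker trajectories (hip joint center, knee, ankle, heel, toe,
metatarsal head, both limbs) are synthesised from segment geometry each
frame, with optional compensation motions (hip hike, circumduction) and
seeded Gaussian marker noise.  Vertical ground-reaction force channels
are synthesised per limb for kinetic event detection.  Noise-free
signals, true event times and true per-stride features are returned as
ground truth for oracle testing of the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (
    DampingCondition,
    ForceChannel,
    MarkerTrajectorySet,
    SwingFeatures,
    TrialBundle,
    marker_label,
)
from .errors import ConfigError, DivergentSwingError

G = 9.80665

#: Damping sweep used by the demo: the coefficient set of the prototype
#: rotary dampers fitted to the reference participant, Nm/(rad/s).
DEFAULT_SWEEP_COEFFICIENTS = (0.0, 0.37, 0.56, 0.80, 1.10)
CONDITION_LABELS = "ABCDEFGH"


def default_sweep_conditions(
    coefficients=DEFAULT_SWEEP_COEFFICIENTS, friction_torque: float = 0.05
) -> list[DampingCondition]:
    """Damping conditions labelled A.. in order of increasing coefficient."""
    return [
        DampingCondition(CONDITION_LABELS[i], float(c), friction_torque)
        for i, c in enumerate(coefficients)
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic gait trial (SI units).

    Geometry defaults approximate a 1.66 m adult; the pendulum
    parameters describe the prosthetic shank+foot as one rigid body
    about the knee axis.  ``nominal_swing_fraction`` is the sound-side
    swing fraction of the stride; the prosthetic swing may exceed it
    when the knee needs longer to re-extend (see ``generate_trial``).
    """

    # segment geometry
    thigh_length: float = 0.43
    shank_length: float = 0.43
    foot_length: float = 0.21
    marker_radius: float = 0.0095
    radius_sign: int = 1
    pelvis_half_width: float = 0.09

    # pendulum (prosthetic shank+foot composite; light ESR build)
    pendulum_mass: float = 2.2
    pendulum_com_distance: float = 0.22
    pendulum_inertia: float = 0.16

    # knee device
    damping: DampingCondition = field(default_factory=DampingCondition)
    bumper_stiffness: float = 400.0
    bumper_damping: float = 15.0

    # gait prescription
    hip_speed: float = 1.24
    hip_height: float = 0.952
    hip_vertical_amplitude: float = 0.012
    stride_period: float = 1.1
    hip_flexion_amplitude: float = 0.35
    hip_flexion_offset: float = 0.05
    nominal_swing_fraction: float = 0.40
    contact_extension_threshold: float = 0.087
    contact_placement_delay: float = 0.04
    swing_pace_offset: float = 0.50
    extension_wait_weight: float = 0.2
    initial_knee_flexion: float = 0.60
    initial_knee_velocity: float = 4.6
    preswing_damping_time: float = 0.14

    # compensations
    hip_hike_amplitude: float = 0.0
    circumduction_amplitude: float = 0.0

    # capture
    marker_noise_sd: float = 0.0005
    seed: int = 0
    kinematic_rate: float = 120.0
    kinetic_rate: float = 960.0
    n_strides: int = 6
    prosthetic_side: str = "right"
    body_mass: float = 68.7
    grf_peak_bw: float = 1.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            ("thigh_length", self.thigh_length),
            ("shank_length", self.shank_length),
            ("foot_length", self.foot_length),
            ("pendulum_mass", self.pendulum_mass),
            ("pendulum_com_distance", self.pendulum_com_distance),
            ("pendulum_inertia", self.pendulum_inertia),
            ("stride_period", self.stride_period),
            ("kinematic_rate", self.kinematic_rate),
            ("kinetic_rate", self.kinetic_rate),
            ("hip_height", self.hip_height),
            ("body_mass", self.body_mass),
        ]
        for name, value in positive:
            if not value > 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if not 0 < self.nominal_swing_fraction < 1:
            raise ConfigError("nominal_swing_fraction must lie in (0, 1)")
        ratio = self.kinetic_rate / self.kinematic_rate
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigError("kinetic_rate must be an integer multiple of kinematic_rate")
        if not self.pendulum_com_distance < self.shank_length + self.foot_length:
            raise ConfigError("pendulum_com_distance must be below shank+foot length")
        if self.n_strides < 3:
            raise ConfigError("n_strides must be >= 3")
        if self.marker_noise_sd < 0:
            raise ConfigError("marker_noise_sd must be >= 0")
        if self.radius_sign not in (-1, 0, 1):
            raise ConfigError("radius_sign must be -1, 0 or +1")
        if self.prosthetic_side not in ("left", "right"):
            raise ConfigError("prosthetic_side must be 'left' or 'right'")
        if self.hip_height <= self.thigh_length + self.shank_length + 0.02:
            raise ConfigError("hip_height must exceed leg length (ankle above floor)")

    # derived quantities -------------------------------------------------
    @property
    def rate_ratio(self) -> int:
        return int(round(self.kinetic_rate / self.kinematic_rate))

    @property
    def ankle_height(self) -> float:
        """Standing ankle joint height above the floor."""
        return self.hip_height - self.thigh_length - self.shank_length

    @property
    def sound_side(self) -> str:
        return "left" if self.prosthetic_side == "right" else "right"

    def foot_local_points(self) -> dict[str, np.ndarray]:
        """Foot landmark positions in the shank-fixed frame at the ankle.

        Expressed for the standing pose (shank vertical): x anterior,
        z up.  Markers sit ~2 cm above the sole; the heel marker is
        posterior of the ankle, the toe marker just short of the tip.
        """
        h = self.ankle_height
        heel_back = 0.06
        return {
            "HEE": np.array([-heel_back, 0.0, -(h - 0.020)]),
            "TOE": np.array([self.foot_length - heel_back - 0.02, 0.0, -(h - 0.020)]),
            "MT": np.array([self.foot_length - heel_back - 0.12, 0.0, -(h - 0.045)]),
        }


@dataclass
class SwingIntegration:
    """Knee flexion trace over one simulated swing (kinetic-rate grid)."""

    t: np.ndarray
    beta: np.ndarray
    betadot: np.ndarray
    damper_power: np.ndarray  # instantaneous power removed by the damper, W

    @property
    def damper_work(self) -> float:
        return float(np.trapezoid(self.damper_power, self.t))


@dataclass
class GroundTruth:
    """Noise-free signals and true event times of one simulated trial."""

    markers: MarkerTrajectorySet
    vtoe: np.ndarray                      # (n_frames, 3) prosthetic virtual toe
    beta: dict[str, np.ndarray]           # knee flexion per side, per frame
    foot_off_s: dict[str, list[float]]
    foot_contact_s: dict[str, list[float]]
    mid_swing_s: dict[str, list[float]]
    ankle_height: float
    features: list[SwingFeatures] = field(default_factory=list)

    def swing_windows(self, side: str) -> list[tuple[float, float]]:
        return list(zip(self.foot_off_s[side], self.foot_contact_s[side]))


@dataclass
class SimOutput:
    """Everything a simulated trial emits."""

    bundle: TrialBundle
    truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# prescribed kinematics
# ---------------------------------------------------------------------------

# Thigh-angle phase lead: the hip reaches peak extension shortly before
# foot off and peak flexion at 40% of the stride after foot off.
_ALPHA_PHASE_LEAD = 0.10
# Hip vertical excursion minima fall near the two foot contacts.
_Z_PHASE = 0.55


def _first_foot_off(config: SimConfig, side: str) -> float:
    """Scheduled first foot-off time of a side (kinetic-grid aligned)."""
    T = config.stride_period
    lead = round(0.6 * T * config.kinematic_rate) / config.kinematic_rate
    t = lead if side == config.prosthetic_side else lead + 0.5 * T
    return round(t * config.kinetic_rate) / config.kinetic_rate


def _thigh_angle(config: SimConfig, t, side: str):
    """Thigh absolute angle (rad, flexion/anterior positive) and derivatives."""
    T = config.stride_period
    u = (np.asarray(t, dtype=float) - _first_foot_off(config, side)) / T
    phase = 2.0 * np.pi * (u + _ALPHA_PHASE_LEAD)
    w = 2.0 * np.pi / T
    a = config.hip_flexion_offset - config.hip_flexion_amplitude * np.cos(phase)
    ad = config.hip_flexion_amplitude * np.sin(phase) * w
    add = config.hip_flexion_amplitude * np.cos(phase) * w * w
    return a, ad, add


def _hip_vertical(config: SimConfig, t):
    """Pelvis vertical position and acceleration (shared by both hips)."""
    T = config.stride_period
    off0 = _first_foot_off(config, config.prosthetic_side)
    w2 = 4.0 * np.pi / T
    theta = w2 * (np.asarray(t, dtype=float) - off0 - _Z_PHASE * T)
    z = config.hip_height - config.hip_vertical_amplitude * np.cos(theta)
    zdd = config.hip_vertical_amplitude * w2 * w2 * np.cos(theta)
    return z, zdd


def prescribe_hip_kinematics(config: SimConfig, t, side: str | None = None):
    """Hip-center position (x, y, z) and thigh absolute angle at time(s) t.

    Walking progresses along +x at constant ``hip_speed``; the pelvis
    oscillates vertically at twice the stride frequency.  Hip-hike and
    circumduction offsets are swing-window gated and applied during
    marker synthesis, not here.
    """
    if side is None:
        side = config.prosthetic_side
    t = np.asarray(t, dtype=float)
    x = config.hip_speed * t
    y = np.full_like(x, config.pelvis_half_width if side == "left"
                     else -config.pelvis_half_width)
    z, _ = _hip_vertical(config, t)
    alpha, _, _ = _thigh_angle(config, t, side)
    return np.stack([x, y, z], axis=-1), alpha


# ---------------------------------------------------------------------------
# prosthetic swing dynamics
# ---------------------------------------------------------------------------

_FRICTION_SMOOTHING = 0.02  # rad/s; Coulomb sign smoothing for fixed-step RK4


def _knee_torque(config: SimConfig, beta: float, betadot: float) -> float:
    """Net knee torque in the flexion-positive sense (device resistance)."""
    c = config.damping.coefficient
    tau = 0.0
    if betadot > 0.0:  # one-way clutch: damping during flexion only
        tau -= c * betadot
    tau -= config.damping.friction_torque * math.tanh(betadot / _FRICTION_SMOOTHING)
    if beta < 0.0:  # extension bumper
        tau -= config.bumper_stiffness * beta + config.bumper_damping * betadot
    return tau


def _pivot_acceleration(config: SimConfig, t: float, side: str):
    """Inertial acceleration of the knee pivot (x, z) from prescribed motion."""
    a, ad, add = _thigh_angle(config, t, side)
    _, zdd = _hip_vertical(config, t)
    lt = config.thigh_length
    sa, ca = math.sin(a), math.cos(a)
    ax = lt * (ca * add - sa * ad * ad)
    az = zdd + lt * (sa * add + ca * ad * ad)
    return ax, az


def _swing_derivative(config: SimConfig, t: float, beta: float, betadot: float,
                      side: str):
    a, ad, add = _thigh_angle(config, t, side)
    phi = a - beta
    akx, akz = _pivot_acceleration(config, t, side)
    m, d, inertia = (config.pendulum_mass, config.pendulum_com_distance,
                     config.pendulum_inertia)
    tau_beta = _knee_torque(config, beta, betadot)
    phidd = (-m * d * (G * math.sin(phi) + akx * math.cos(phi)
                       + akz * math.sin(phi)) - tau_beta) / inertia
    betadd = add - phidd
    return betadot, betadd


def integrate_swing(
    config: SimConfig,
    t_off: float = 0.0,
    beta0: float | None = None,
    betadot0: float | None = None,
    duration: float | None = None,
    side: str | None = None,
) -> SwingIntegration:
    """Integrate the swing-knee flexion angle from foot off.

    Composite shank+foot pendulum about the moving knee pivot (gravity
    plus pivot-acceleration terms) with the device torques of
    ``_knee_torque``.  Fixed-step classical Runge-Kutta at the kinetic
    sampling interval; deterministic by construction.
    """
    if side is None:
        side = config.prosthetic_side
    if beta0 is None:
        beta0 = config.initial_knee_flexion
    if betadot0 is None:
        betadot0 = config.initial_knee_velocity
    if duration is None:
        duration = 0.85 * config.stride_period
    dt = 1.0 / config.kinetic_rate
    n = int(round(duration / dt))
    t = t_off + dt * np.arange(n + 1)
    beta = np.empty(n + 1)
    betadot = np.empty(n + 1)
    beta[0], betadot[0] = beta0, betadot0
    b, bd = float(beta0), float(betadot0)
    for i in range(n):
        ti = t[i]
        k1 = _swing_derivative(config, ti, b, bd, side)
        k2 = _swing_derivative(config, ti + dt / 2, b + dt / 2 * k1[0],
                               bd + dt / 2 * k1[1], side)
        k3 = _swing_derivative(config, ti + dt / 2, b + dt / 2 * k2[0],
                               bd + dt / 2 * k2[1], side)
        k4 = _swing_derivative(config, ti + dt, b + dt * k3[0],
                               bd + dt * k3[1], side)
        b += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        bd += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if abs(b) > math.pi:
            raise DivergentSwingError(
                f"knee flexion left the physical range at t={ti:.3f}s "
                f"(beta={b:.2f} rad); configuration invalid")
        beta[i + 1], betadot[i + 1] = b, bd
    power = np.where(betadot > 0,
                     config.damping.coefficient * betadot**2, 0.0)
    return SwingIntegration(t=t, beta=beta, betadot=betadot, damper_power=power)


def _extension_crossing(sw: SwingIntegration, threshold: float) -> float | None:
    """Time the knee first re-extends below ``threshold`` after peak flexion."""
    ipk = int(np.argmax(sw.beta))
    below = np.nonzero(sw.beta[ipk:] < threshold)[0]
    if below.size == 0:
        return None
    j = ipk + below[0]
    if j == 0:
        return float(sw.t[0])
    b0, b1 = sw.beta[j - 1], sw.beta[j]
    frac = (b0 - threshold) / (b0 - b1) if b1 != b0 else 0.0
    return float(sw.t[j - 1] + frac * (sw.t[j] - sw.t[j - 1]))


def _quintic(t, t0, t1, y0, v0, y1, v1):
    """Quintic Hermite with zero end accelerations, evaluated at t."""
    h = t1 - t0
    s = (np.asarray(t, dtype=float) - t0) / h
    s2, s3, s4, s5 = s**2, s**3, s**4, s**5
    h00 = 1 - 10 * s3 + 15 * s4 - 6 * s5
    h10 = s - 6 * s3 + 8 * s4 - 3 * s5
    h01 = 10 * s3 - 15 * s4 + 6 * s5
    h11 = -4 * s3 + 7 * s4 - 3 * s5
    return y0 * h00 + v0 * h * h10 + y1 * h01 + v1 * h * h11


# ---------------------------------------------------------------------------
# ground-reaction force
# ---------------------------------------------------------------------------

_STANCE_REST_FLEXION = 0.06  # rad; relaxed stance-phase knee flexion


def swing_initial_state(config: SimConfig) -> tuple[float, float]:
    """Knee state imparted to the swing by late stance, damping-dependent.

    The flexion damper engages as soon as the knee starts flexing in
    pre-swing, so higher coefficients enter swing with less flexion and
    velocity.  Modelled as a first-order admittance: the zero-damping
    initial state is attenuated by I/(I + c*t_pre), where t_pre is the
    effective pre-swing flexion duration.
    """
    att = config.pendulum_inertia / (
        config.pendulum_inertia
        + config.damping.coefficient * config.preswing_damping_time)
    # the toe-off angle is partly forced by trailing-limb geometry, so it
    # attenuates more weakly than the flexion velocity
    beta0 = _STANCE_REST_FLEXION + (config.initial_knee_flexion
                                    - _STANCE_REST_FLEXION) * math.sqrt(att)
    return beta0, config.initial_knee_velocity * att


_GRF_RAMP = 0.04  # s; raised-cosine load/unload ramp at stance edges
FOOT_OFF_THRESHOLD_N = 5.0


def synthesize_grf(config: SimConfig, stance_windows, n_samples: int,
                   side: str) -> tuple[ForceChannel, list[float]]:
    """Vertical GRF: raised-cosine edged plateau per stance window.

    Returns the channel and the analytic 5 N down-crossing time of each
    window that ends inside the trial (the kinetic foot-off times).
    """
    windows = sorted(stance_windows)
    for (a0, b0), (a1, _) in zip(windows, windows[1:]):
        if a1 < b0:
            raise ConfigError("stance windows overlap")
    t = np.arange(n_samples) / config.kinetic_rate
    f = np.zeros(n_samples)
    peak = config.grf_peak_bw * config.body_mass * G
    r = _GRF_RAMP
    crossings: list[float] = []
    for a, b in windows:
        inside = (t >= a) & (t <= b)
        w = np.ones(inside.sum())
        ts = t[inside]
        rise = ts < a + r
        fall = ts > b - r
        w[rise] = 0.5 * (1 - np.cos(np.pi * (ts[rise] - a) / r))
        w[fall] = 0.5 * (1 - np.cos(np.pi * (b - ts[fall]) / r))
        f[inside] = peak * w
        if b < t[-1]:
            u = (r / np.pi) * math.acos(1 - 2 * FOOT_OFF_THRESHOLD_N / peak)
            crossings.append(b - u)
    return ForceChannel(rate=config.kinetic_rate, side=side, fz=f), crossings


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _sound_beta(config: SimConfig, t):
    """Prescribed sound-limb knee flexion: periodic swing/stance bumps."""
    T = config.stride_period
    f = config.nominal_swing_fraction
    u = ((np.asarray(t, dtype=float) - _first_foot_off(config, config.sound_side))
         / T) % 1.0
    beta = np.empty_like(u)
    swing = u < f
    s = (u[swing] / f) ** 1.3  # skewed bump: flexion peaks past mid-swing,
    beta[swing] = 0.06 + 1.0 * np.sin(np.pi * s) ** 2  # high late clearance
    v = (u[~swing] - f) / (1 - f)
    beta[~swing] = 0.06 + 0.10 * np.sin(np.pi * v) ** 2
    return beta


def _flat_top_window(t, t0, t1, rise_frac=0.10, fall_frac=None):
    """Smooth 0->1->0 window over [t0, t1] with cosine rise/fall."""
    if fall_frac is None:
        fall_frac = rise_frac
    s = np.clip((np.asarray(t, dtype=float) - t0) / (t1 - t0), 0.0, 1.0)
    w = np.ones_like(s)
    rise = s < rise_frac
    fall = s > 1 - fall_frac
    w[rise] = 0.5 * (1 - np.cos(np.pi * s[rise] / rise_frac))
    w[fall] = 0.5 * (1 - np.cos(np.pi * (1 - s[fall]) / fall_frac))
    w[(s <= 0) | (s >= 1)] = 0.0
    return w


# Landing window: a smooth pull from the raw swing trajectory into a
# constant-speed glide that ends in a corner at the contact instant.
# The prosthetic side uses a short window so mid-swing toe-clearance
# metrics are untouched; the sound side (shorter, steeper swing) needs a
# longer deceleration to stay inside the low-pass band.
_LANDING_RAMP = {"pros": 0.28, "sound": 0.32}   # s
_LANDING_GLIDE = {"pros": 0.08, "sound": 0.12}  # s
_LANDING_SPEED = {"pros": 0.093, "sound": 0.10}  # m/s approach speed at the corner
_LANDING_GLIDE = {"pros": 0.16, "sound": 0.07}
                       # s; constant-slope glide so the filtered velocity
                       # settles on the approach speed before the corner
_LANDING_CLEARANCE = 0.022  # m; minimum ankle clearance entering the descent
_LANDING_ONSET = 0.08       # s; smooth engage of the step-over lift
_LANDING_FLAT_FRAC = 0.30  # fraction of stance with the ankle pinned at h_a


def _smootherstep(s: np.ndarray) -> np.ndarray:
    """C2 monotone 0->1 blend; keeps landing transients inside the
    low-pass band so filtering does not displace the contact instant."""
    s = np.clip(s, 0.0, 1.0)
    return s * s * s * (s * (6.0 * s - 15.0) + 10.0)


def _rot_sagittal(phi):
    """Apply the sagittal rotation (about +y, anterior tilt positive)."""
    c, s = np.cos(phi), np.sin(phi)
    return c, s


def _place_limb(config: SimConfig, t, side: str, beta, swings,
                vtoe_local: np.ndarray | None):
    """Forward kinematics of one limb at the kinematic frames.

    Returns dict of marker name -> (n, 3) plus the rigid virtual-toe
    trace when ``vtoe_local`` (shank-frame coordinates at the ankle) is
    given.  Applies swing-gated hip hike / circumduction and the
    landing correction that brings the ankle to standing height at each
    foot contact (absorbed as pelvic obliquity of that side).
    """
    t = np.asarray(t, dtype=float)
    hip, alpha = prescribe_hip_kinematics(config, t, side)
    hip = hip.copy()
    phi = alpha - beta

    # compensations, prosthetic side only, gated to its swing windows:
    # quick engage, plateau through the toe-clearance minimum, slow
    # release completing exactly at foot contact.  The hike rides on top
    # of the hike-free landing solution, so the ankle still lands at
    # standing height; its slow release slightly steepens the final
    # approach when enabled.
    dz = np.zeros_like(t)
    dy = np.zeros_like(t)
    if side == config.prosthetic_side:
        for a, b in swings:
            dz += config.hip_hike_amplitude * _flat_top_window(
                t, a, b, rise_frac=0.10, fall_frac=0.35)
            dy += config.circumduction_amplitude * _flat_top_window(t, a, b)
    ysign = 1.0 if side == "left" else -1.0

    lt, ls = config.thigh_length, config.shank_length
    ca, sa = np.cos(alpha), np.sin(alpha)
    cp, sp = _rot_sagittal(phi)
    knee = hip + lt * np.stack([sa, np.zeros_like(sa), -ca], axis=1)
    ankle = knee + ls * np.stack([sp, np.zeros_like(sp), -cp], axis=1)

    # landing correction: bring the ankle onto the floor at foot contact
    # with a constant-speed final glide ending in a corner at the contact
    # instant, then pin it at standing height through early stance
    h_a = config.ankle_height
    raw_z = ankle[:, 2].copy()
    corr = np.zeros_like(raw_z)
    role = "pros" if side == config.prosthetic_side else "sound"
    ramp = _LANDING_RAMP[role]
    speed = _LANDING_SPEED[role]
    raw_vz = np.gradient(raw_z, t) if t.size > 1 else np.zeros_like(raw_z)
    for a, b in swings:
        stance_end = b + _LANDING_FLAT_FRAC * (config.stride_period
                                               * (1 - config.nominal_swing_fraction))
        # one C1 cubic Hermite descent from the raw swing state into the
        # corner: value h_a and slope -speed exactly at the contact
        # instant, flat at h_a afterwards.  The sub-6-Hz descent keeps
        # the filtered velocity on the raw profile, so the detector's
        # velocity criterion fires at the corner.
        g = _LANDING_GLIDE[role]
        t0, t1 = b - ramp, b - g
        span = ramp - g
        z0 = float(np.interp(t0, t, raw_z))
        v0 = float(np.interp(t0, t, raw_vz))
        lifted = z0 < h_a + _LANDING_CLEARANCE
        if lifted:
            # terminal-swing step-over: guarantee enough clearance that
            # the descent through the detector's height band happens at
            # the glide speed, not in a slow skim
            z0 = h_a + _LANDING_CLEARANCE
            v0 = min(v0, 0.0)
        s = np.clip((t - t0) / span, 0.0, 1.0)
        s2, s3 = s * s, s ** 3
        desired = ((2 * s3 - 3 * s2 + 1) * z0
                   + (s3 - 2 * s2 + s) * span * v0
                   + (-2 * s3 + 3 * s2) * (h_a + speed * g)
                   + (s3 - s2) * span * (-speed))
        glide = h_a + speed * np.maximum(b - t, 0.0)
        desired = np.where(t >= t1, glide, desired)
        w_on = (_smootherstep((t - (t0 - _LANDING_ONSET)) / _LANDING_ONSET)
                if lifted else np.ones_like(t))
        w_rel = 1.0 - _smootherstep((t - stance_end) / ramp)
        active = (t >= (t0 - _LANDING_ONSET if lifted else t0)) \
            & (t <= stance_end + ramp)
        corr += np.where(active, w_on * w_rel * (desired - raw_z), 0.0)
    # initial stance before the first swing: hold the ankle at h_a
    if swings:
        first_off = swings[0][0]
        w0 = 1.0 - _smootherstep(
            (t - (first_off - 0.35 * config.stride_period)) / ramp)
        w0[t > first_off] = 0.0
        corr += w0 * (h_a - raw_z)

    shift = np.stack([np.zeros_like(corr), np.zeros_like(corr),
                      corr + dz], axis=1)
    hip = hip + shift
    knee = knee + shift
    ankle = ankle + shift

    knee[:, 1] += ysign * 0.5 * dy
    ankle[:, 1] += ysign * dy

    out = {"HJC": hip, "KNE": knee, "ANK": ankle}
    for name, p in config.foot_local_points().items():
        px, pz = p[0], p[2]
        rx = px * cp - pz * sp
        rz = px * sp + pz * cp
        pt = ankle + np.stack([rx, np.full_like(rx, p[1]), rz], axis=1)
        out[name] = pt
    vtoe = None
    if vtoe_local is not None:
        px, pz = vtoe_local[0], vtoe_local[2]
        rx = px * cp - pz * sp
        rz = px * sp + pz * cp
        vtoe = ankle + np.stack([rx, np.full_like(rx, vtoe_local[1]), rz], axis=1)
    return out, vtoe


def _standing_frame(config: SimConfig) -> MarkerTrajectorySet:
    """Single-frame neutral standing pose of both limbs."""
    labels, pos = [], []
    for side in ("left", "right"):
        ysign = 1.0 if side == "left" else -1.0
        hip = np.array([0.0, ysign * config.pelvis_half_width, config.hip_height])
        knee = hip + np.array([0, 0, -config.thigh_length])
        ankle = knee + np.array([0, 0, -config.shank_length])
        pts = {"HJC": hip, "KNE": knee, "ANK": ankle}
        for name, p in config.foot_local_points().items():
            pts[name] = ankle + p
        for name in ("HJC", "KNE", "ANK", "HEE", "TOE", "MT"):
            labels.append(marker_label(side, name))
            pos.append(pts[name])
    return MarkerTrajectorySet(config.kinematic_rate, labels,
                               np.asarray(pos)[None, :, :])


def _vtoe_local(config: SimConfig) -> np.ndarray:
    """Virtual-toe coordinates in the shank frame at the ankle.

    Constructed exactly as the analysis pipeline constructs it from the
    standing calibration: heel and toe markers projected onto the floor,
    the landmark placed on the projected heel->toe axis at
    foot_length + radius_sign*marker_radius from the projected heel.
    """
    pts = config.foot_local_points()
    ankle = np.array([0.0, 0.0, config.ankle_height])
    heel = ankle + pts["HEE"]
    toe = ankle + pts["TOE"]
    heel_floor = np.array([heel[0], heel[1], 0.0])
    toe_floor = np.array([toe[0], toe[1], 0.0])
    axis = toe_floor - heel_floor
    axis /= np.linalg.norm(axis)
    dist = config.foot_length + config.radius_sign * config.marker_radius
    vtoe = heel_floor + dist * axis
    return vtoe - ankle  # shank-frame local coordinates (standing pose)


def _interp_crossing(t, y) -> float | None:
    """First sign change of y (negative -> positive), linearly interpolated."""
    s = np.sign(y)
    idx = np.nonzero((s[:-1] < 0) & (s[1:] >= 0))[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if y[i + 1] == y[i]:
        return float(t[i])
    return float(t[i] - y[i] * (t[i + 1] - t[i]) / (y[i + 1] - y[i]))


def generate_trial(config: SimConfig) -> SimOutput:
    """Simulate one trial: markers, forces, standing frame, ground truth.

    Foot contact on the prosthetic side follows the behavioural rule:
    the user places the foot a fixed short delay after the knee first
    re-extends below ``contact_extension_threshold``, but never before
    the nominal swing end - so low damping (slow re-extension) prolongs
    prosthetic swing.  Identical configs and seeds give identical output.
    """
    T = config.stride_period
    fr = config.kinematic_rate
    off0 = _first_foot_off(config, config.prosthetic_side)
    duration = off0 + config.n_strides * T + 0.4 * T
    n_frames = int(round(duration * fr)) + 1
    t_frames = np.arange(n_frames) / fr
    n_kin = (n_frames - 1) * config.rate_ratio + 1

    # ---- prosthetic swing dynamics, stride schedule -------------------
    pros = config.prosthetic_side
    pros_offs = [round((off0 + i * T) * config.kinetic_rate) / config.kinetic_rate
                 for i in range(config.n_strides)]
    swings: list[tuple[float, float]] = []
    segments = []  # (t_off, t_c, SwingIntegration, state at t_c)
    b0, bd0 = swing_initial_state(config)
    for t_off in pros_offs:
        sw = integrate_swing(config, t_off=t_off, beta0=b0, betadot0=bd0)
        t_ext = _extension_crossing(sw, config.contact_extension_threshold)
        nominal_end = t_off + config.nominal_swing_fraction * T
        if t_ext is None:
            t_c = t_off + 0.82 * T
        else:
            # paced landing: the user's habitual prosthetic swing duration
            # plus a weighted wait on knee re-extension, never before the
            # nominal swing end nor before the knee has settled extended
            s_ext = t_ext - t_off
            t_c = t_off + max(
                config.nominal_swing_fraction * T,
                config.swing_pace_offset
                + config.extension_wait_weight * s_ext,
                s_ext + config.contact_placement_delay,
            )
            t_c = min(t_c, t_off + 0.82 * T)
        # contact lands on the kinematic capture grid
        t_c = round(t_c * fr) / fr
        bc = float(np.interp(t_c, sw.t, sw.beta))
        bdc = float(np.interp(t_c, sw.t, sw.betadot))
        swings.append((t_off, t_c))
        segments.append((t_off, t_c, sw, (bc, bdc)))

    # prosthetic knee flexion at the kinematic frames (piecewise):
    # swing dynamics, then a two-part stance (settle to the rest angle,
    # pre-swing rise to the next initial state) that cannot dip into
    # hyperextension the way a single end-to-end blend would
    beta_pros = np.empty(n_frames)
    rest = _STANCE_REST_FLEXION

    def stance_blend(mask, t_a, t_b, state_a, state_b):
        if not np.any(mask):
            return
        t_mid = 0.5 * (t_a + t_b)
        early = mask & (t_frames <= t_mid)
        late = mask & (t_frames > t_mid)
        beta_pros[early] = _quintic(t_frames[early], t_a, t_mid,
                                    state_a[0], state_a[1], rest, 0.0)
        beta_pros[late] = _quintic(t_frames[late], t_mid, t_b,
                                   rest, 0.0, state_b[0], state_b[1])

    lead_mask = t_frames <= swings[0][0]
    t_rise = 0.5 * swings[0][0]
    hold = lead_mask & (t_frames <= t_rise)
    rise = lead_mask & (t_frames > t_rise)
    beta_pros[hold] = rest
    beta_pros[rise] = _quintic(t_frames[rise], t_rise, swings[0][0],
                               rest, 0.0, b0, bd0)
    for i, (t_off, t_c, sw, (bc, bdc)) in enumerate(segments):
        m = (t_frames > t_off) & (t_frames <= t_c)
        beta_pros[m] = np.interp(t_frames[m], sw.t, sw.beta)
        t_next = segments[i + 1][0] if i + 1 < len(segments) else t_frames[-1]
        m = (t_frames > t_c) & (t_frames <= t_next)
        stance_blend(m, t_c, t_next, (bc, bdc),
                     (b0, bd0) if i + 1 < len(segments) else (rest, 0.0))

    # ---- sound side ---------------------------------------------------
    sound = config.sound_side
    beta_sound = _sound_beta(config, t_frames)
    sound_off0 = _first_foot_off(config, sound)
    sound_swings = []
    i = 0
    while True:
        a = round((sound_off0 + i * T) * config.kinetic_rate) / config.kinetic_rate
        b = a + config.nominal_swing_fraction * T
        if b > duration - 0.1 * T:
            break
        sound_swings.append((a, b))
        i += 1

    # ---- marker synthesis ---------------------------------------------
    vtoe_local = _vtoe_local(config)
    pros_pts, vtoe = _place_limb(config, t_frames, pros, beta_pros, swings,
                                 vtoe_local)
    sound_pts, _ = _place_limb(config, t_frames, sound, beta_sound,
                               sound_swings, None)
    labels, clean = [], []
    for side, pts in ((( "left"), pros_pts if pros == "left" else sound_pts),
                      (("right"), pros_pts if pros == "right" else sound_pts)):
        for name in ("HJC", "KNE", "ANK", "HEE", "TOE", "MT"):
            labels.append(marker_label(side, name))
            clean.append(pts[name])
    clean = np.stack(clean, axis=1)  # (frames, markers, 3)

    noisy = clean.copy()
    if config.marker_noise_sd > 0:
        children = np.random.SeedSequence(config.seed).spawn(len(labels))
        for j, child in enumerate(children):
            rng = np.random.default_rng(child)
            noisy[:, j, :] += rng.normal(0.0, config.marker_noise_sd,
                                         size=(n_frames, 3))

    truth_markers = MarkerTrajectorySet(fr, list(labels), clean)
    trial = MarkerTrajectorySet(fr, list(labels), noisy)

    # ---- forces --------------------------------------------------------
    def stance_windows(swing_list):
        w, prev = [], 0.0
        for a, b in swing_list:
            if a > prev:
                w.append((prev, a))
            prev = b
        if prev < duration:
            w.append((prev, duration))
        return w

    forces: dict[str, ForceChannel] = {}
    foot_off_s: dict[str, list[float]] = {}
    for side, swing_list in ((pros, swings), (sound, sound_swings)):
        ch, crossings = synthesize_grf(config, stance_windows(swing_list),
                                       n_kin, side)
        forces[side] = ch
        foot_off_s[side] = crossings[: len(swing_list)]

    # ---- truth events ---------------------------------------------------
    foot_contact_s = {pros: [b for _, b in swings],
                      sound: [b for _, b in sound_swings]}
    walk_dir = np.array([1.0, 0.0, 0.0])
    mid_swing_s: dict[str, list[float]] = {pros: [], sound: []}
    for side, other, swing_list in ((pros, sound, swings),
                                    (sound, pros, sound_swings)):
        a_sw = (pros_pts if side == pros else sound_pts)["ANK"] @ walk_dir
        a_st = (pros_pts if other == pros else sound_pts)["ANK"] @ walk_dir
        for a, b in swing_list:
            m = (t_frames >= a) & (t_frames <= b)
            tc = _interp_crossing(t_frames[m], (a_sw - a_st)[m])
            mid_swing_s[side].append(tc if tc is not None else 0.5 * (a + b))

    truth = GroundTruth(
        markers=truth_markers,
        vtoe=vtoe,
        beta={pros: beta_pros, sound: beta_sound},
        foot_off_s=foot_off_s,
        foot_contact_s=foot_contact_s,
        mid_swing_s=mid_swing_s,
        ankle_height=config.ankle_height,
    )
    truth.features = _truth_features(config, truth)

    bundle = TrialBundle(
        trial=trial,
        forces=forces,
        standing=_standing_frame(config),
        foot_length=config.foot_length,
        marker_radius=config.marker_radius,
        prosthetic_side=pros,
        condition=config.damping,
    )
    return SimOutput(bundle=bundle, truth=truth, config=config)


def _truth_features(config: SimConfig, truth: GroundTruth) -> list[SwingFeatures]:
    """Per-stride features computed from the noise-free signals."""
    from . import metrics  # local import: metrics is pure geometry

    pros, sound = config.prosthetic_side, config.sound_side
    fr = config.kinematic_rate
    hip = truth.markers.marker(marker_label(pros, "HJC"))
    knee = truth.markers.marker(marker_label(pros, "KNE"))
    ankle = truth.markers.marker(marker_label(pros, "ANK"))
    midhip = 0.5 * (truth.markers.marker(marker_label("left", "HJC"))
                    + truth.markers.marker(marker_label("right", "HJC")))
    direction = np.array([1.0, 0.0, 0.0])
    speed = metrics.walking_speed(midhip, direction, fr)
    sound_sw = [b - a for a, b in truth.swing_windows(sound)]
    sound_mid = [0.5 * (a + b) for a, b in truth.swing_windows(sound)]

    out = []
    for k, (a, b) in enumerate(truth.swing_windows(pros)):
        i0, i1 = int(round(a * fr)), int(round(b * fr))
        idx = np.arange(i0, i1 + 1)
        tt = idx / fr
        prof = metrics.swing_profile_from_traces(
            t=tt,
            hip=hip[idx], knee=knee[idx], ankle=ankle[idx], vtoe=truth.vtoe[idx],
            direction=direction,
            t_off=a, t_contact=b, t_msw=truth.mid_swing_s[pros][k],
            gamma=np.zeros(idx.size),
        )
        j = int(np.argmin(np.abs(np.array(sound_mid) - truth.mid_swing_s[pros][k]))) \
            if sound_mid else 0
        sts = metrics.swing_time_symmetry(b - a, sound_sw[j]) if sound_sw else 50.0
        feats = metrics.extract_features(
            prof, stride_id=k, condition=config.damping.label,
            coefficient=config.damping.coefficient, sts_pct=sts)
        i_tc = i0 + int(round(feats.tc_min_t_pct / 100 * (i1 - i0)))
        feats.walking_speed_m_s = speed
        feats.hip_height_at_tc_min_m = float(hip[i_tc, 2])
        feats.lateral_hip_ankle_at_tc_min_m = float(abs(hip[i_tc, 1]
                                                        - ankle[i_tc, 1]))
        out.append(feats)
    return out


def sweep_damping(config: SimConfig, conditions) -> list[SimOutput]:
    """One trial per damping condition; seeds offset by condition index."""
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ConfigError("need at least two damping conditions")
    coeffs = [c.coefficient for c in conditions]
    if len(set(coeffs)) != len(coeffs):
        raise ConfigError("damping coefficients must be distinct")
    out = []
    for i, cond in enumerate(conditions):
        cfg = replace(config, damping=cond, seed=config.seed + i)
        out.append(generate_trial(cfg))
    return out
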