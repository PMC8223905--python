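"""Swing-phase profiles and per-stride scalar features.

All operations act on sagittal-plane coordinates defined by the walking
direction (anterior x = position projected on the unit walking vector,
vertical z = lab z).  Angle conventions: hip flexion ``alpha`` is the
thigh's anterior tilt from the downward vertical; knee flexion ``beta``
is the posterior rotation of the shank relative to the thigh (zero when
collinear); ankle dorsiflexion ``gamma`` is the toe-up rotation of the
foot relative to the shank, expressed as deviation from the standing
calibration posture.  All argmin/argmax ties break toward the earlier
frame for determinism.
"""

from __future__ import annotations

import numpy as np

from .containers import PERCENT_GRID, Stride, SwingFeatures, SwingProfile
from .errors import DegenerateGeometryError, ProswingError


def compute_ell(hip: np.ndarray, vtoe: np.ndarray) -> np.ndarray:
    """Effective leg length: 3-D Euclidean hip-to-virtual-toe distance.

    ``hip`` and ``vtoe`` are (n, 3).  A sagittal-projected variant is
    available via :func:`compute_ell_sagittal` for sensitivity analysis.
    """
    return np.linalg.norm(np.asarray(hip) - np.asarray(vtoe), axis=-1)


def compute_ell_sagittal(hip: np.ndarray, vtoe: np.ndarray,
                         direction: np.ndarray) -> np.ndarray:
    """Effective leg length in the sagittal (walking-direction/vertical) plane."""
    d = np.asarray(direction, dtype=float)[:3]
    d = d / np.linalg.norm(d)
    dx = (np.asarray(hip) - np.asarray(vtoe)) @ d
    dz = np.asarray(hip)[:, 2] - np.asarray(vtoe)[:, 2]
    return np.hypot(dx, dz)


def compute_tc(vtoe: np.ndarray) -> np.ndarray:
    """Toe clearance: vertical virtual-toe height above the floor (z = 0).

    Negative values (estimated floor penetration) are preserved, never
    clamped: they are diagnostically meaningful.
    """
    return np.asarray(vtoe)[..., 2].copy()


def _sagittal(p: np.ndarray, direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.zeros(3)
    d[: len(np.asarray(direction))] = np.asarray(direction, dtype=float)
    d[2] = 0.0
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("walking direction must have a floor-plane component")
    d /= n
    p = np.asarray(p, dtype=float)
    return p @ d, p[..., 2]


def _segment_angle(dx: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """Anterior tilt of a segment direction from the downward vertical."""
    if np.any(np.hypot(dx, dz) < 1e-12):
        raise DegenerateGeometryError("zero-length segment in sagittal plane")
    return np.unwrap(np.arctan2(dx, -dz))


def compute_joint_angles(
    hip: np.ndarray,
    knee: np.ndarray,
    ankle: np.ndarray,
    toe: np.ndarray,
    direction: np.ndarray,
    standing_foot_offset: float = 0.0,
):
    """Sagittal hip, knee and ankle angle traces from joint-center paths.

    Returns ``(alpha, beta, gamma)`` in radians.  ``standing_foot_offset``
    is the foot-relative-to-shank angle of the standing calibration;
    ``gamma`` is the deviation from it (dorsiflexion positive).
    """
    xh, zh = _sagittal(hip, direction)
    xk, zk = _sagittal(knee, direction)
    xa, za = _sagittal(ankle, direction)
    xt, zt = _sagittal(toe, direction)
    alpha = _segment_angle(xk - xh, zk - zh)
    shank = _segment_angle(xa - xk, za - zk)
    beta = alpha - shank
    # foot angle measured from the anterior horizontal, toe-up positive
    foot = np.unwrap(np.arctan2(zt - za, xt - xa))
    gamma = (foot - shank) - standing_foot_offset
    return alpha, beta, np.unwrap(gamma)


def standing_foot_shank_offset(knee, ankle, toe, direction) -> float:
    """Foot-to-shank angle of a single calibration frame (see above)."""
    xk, zk = _sagittal(np.atleast_2d(knee), direction)
    xa, za = _sagittal(np.atleast_2d(ankle), direction)
    xt, zt = _sagittal(np.atleast_2d(toe), direction)
    shank = _segment_angle(xa - xk, za - zk)
    foot = np.arctan2(zt - za, xt - xa)
    return float(foot[0] - shank[0])


def compute_tzs(x_hip, x_kne, x_ank, x_toe):
    """Sensitivity of vertical toe position to hip/knee/ankle rotation.

    Planar partial derivatives of toe height with respect to hip
    flexion, knee flexion and ankle dorsiflexion (m/rad):

        dz_toe/d(alpha) = x_toe - x_hip
        dz_toe/d(beta)  = x_kne - x_toe
        dz_toe/d(gamma) = x_toe - x_ank

    Each follows from rotating the chain distal to the joint about the
    lab's medial-lateral axis.
    """
    x_hip, x_kne = np.asarray(x_hip, float), np.asarray(x_kne, float)
    x_ank, x_toe = np.asarray(x_ank, float), np.asarray(x_toe, float)
    return x_toe - x_hip, x_kne - x_toe, x_toe - x_ank


def normalize_swing(t: np.ndarray, traces: dict[str, np.ndarray],
                    t_off: float, t_contact: float):
    """Resample traces onto the integer 0..100 percent-swing grid.

    Linear interpolation; ``t`` must cover [t_off, t_contact].
    """
    if not t_contact > t_off:
        raise ValueError("foot contact must follow foot off")
    t = np.asarray(t, dtype=float)
    if t.size < 10:
        raise ProswingError("degenerate swing window (< 10 frames)")
    pct = 100.0 * (t - t_off) / (t_contact - t_off)
    return {k: np.interp(PERCENT_GRID, pct, np.asarray(v, float))
            for k, v in traces.items()}


def swing_profile_from_traces(
    t: np.ndarray,
    hip: np.ndarray,
    knee: np.ndarray,
    ankle: np.ndarray,
    vtoe: np.ndarray,
    direction: np.ndarray,
    t_off: float,
    t_contact: float,
    t_msw: float,
    gamma: np.ndarray | None = None,
    standing_foot_offset: float = 0.0,
    toe: np.ndarray | None = None,
    stride: Stride | None = None,
) -> SwingProfile:
    """Assemble the swing-normalized profile of one stride.

    ``gamma`` may be supplied directly (e.g. for a passive rigid ankle);
    otherwise it is computed from the toe marker trajectory.
    """
    ell = compute_ell(hip, vtoe)
    tc = compute_tc(vtoe)
    if gamma is None:
        if toe is None:
            raise ValueError("either gamma or a toe trajectory is required")
        alpha, beta, gamma = compute_joint_angles(
            hip, knee, ankle, toe, direction, standing_foot_offset)
    else:
        alpha, beta, _ = compute_joint_angles(
            hip, knee, ankle, vtoe, direction, standing_foot_offset)
    xh, _ = _sagittal(hip, direction)
    xk, _ = _sagittal(knee, direction)
    xa, _ = _sagittal(ankle, direction)
    xt, _ = _sagittal(vtoe, direction)
    tzs_hip, tzs_kne, tzs_ank = compute_tzs(xh, xk, xa, xt)
    traces = normalize_swing(
        t,
        {"ell": ell, "tc": tc, "alpha": alpha, "beta": beta, "gamma": gamma,
         "tzs_hip": tzs_hip, "tzs_kne": tzs_kne, "tzs_ank": tzs_ank},
        t_off, t_contact)
    msw_pct = 100.0 * (t_msw - t_off) / (t_contact - t_off)
    if stride is None:
        rate = (t.size - 1) / (t[-1] - t[0]) if t.size > 1 else 0.0
        stride = Stride("", int(round(t_off * rate)), int(round(t_contact * rate)))
    return SwingProfile(
        stride=stride, grid=PERCENT_GRID.astype(float), msw_pct=float(msw_pct),
        **traces)


def swing_time_symmetry(t_prosthetic: float, t_sound: float) -> float:
    """Prosthetic swing duration as % of summed swing durations.

    50% indicates perfect symmetry; values above 50% a longer prosthetic
    swing.
    """
    if t_prosthetic <= 0 or t_sound <= 0:
        raise ValueError("swing durations must be positive")
    return 100.0 * t_prosthetic / (t_prosthetic + t_sound)


def walking_speed(midhip: np.ndarray, direction: np.ndarray,
                  rate: float) -> float:
    """Mean progression speed of the mid-hip point along the walk direction.

    The mid-hip point stands in for the whole-body center of mass.
    """
    x, _ = _sagittal(midhip, direction)
    if x.size < 2:
        raise ValueError("need at least two frames")
    return float((x[-1] - x[0]) / ((x.size - 1) / rate))


def extract_features(
    profile: SwingProfile,
    stride_id: int,
    condition: str,
    coefficient: float,
    sts_pct: float,
) -> SwingFeatures:
    """Scalar outcome set of one stride from its swing profile.

    Timing of maximum knee extension is searched from the frame of peak
    knee flexion to the end of swing (terminal swing), so an extended
    knee at swing onset is never selected.  Relative timings are
    feature time minus mid-swing time (positive = after mid-swing).
    """
    if profile.stride is not None and profile.stride.flags:
        raise ProswingError(
            f"refusing flagged stride {stride_id}: {profile.stride.flags}")
    grid = profile.grid
    ell_max_i = int(np.argmax(profile.ell))
    tc_min_i = int(np.argmin(profile.tc))
    pk = int(np.argmax(profile.beta))
    ke_max_i = pk + int(np.argmin(profile.beta[pk:]))
    msw = profile.msw_pct
    return SwingFeatures(
        stride=stride_id,
        condition=condition,
        coefficient=coefficient,
        ell_min_m=float(np.min(profile.ell)),
        tc_min_m=float(np.min(profile.tc)),
        ell_max_t_pct=float(grid[ell_max_i]),
        tc_min_t_pct=float(grid[tc_min_i]),
        ke_max_t_pct=float(grid[ke_max_i]),
        msw_t_pct=float(msw),
        ell_max_t_rel_msw_pct=float(grid[ell_max_i] - msw),
        tc_min_t_rel_msw_pct=float(grid[tc_min_i] - msw),
        sts_pct=float(sts_pct),
        tzs_hip_m_per_rad=float(profile.tzs_hip[tc_min_i]),
        tzs_kne_m_per_rad=float(profile.tzs_kne[tc_min_i]),
        tzs_ank_m_per_rad=float(profile.tzs_ank[tc_min_i]),
    )
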