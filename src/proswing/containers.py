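"""Core data containers shared across the pipeline.

Coordinate convention (fixed at read time, used everywhere internally):
x anterior (walking direction), y lateral-left, z vertical up, origin on
the laboratory floor plane; all lengths in meters, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingMarkerError

#: Marker names required on each limb.  ``HJC`` is the hip joint center
#: (supplied, not estimated), ``KNE``/``ANK`` the knee and ankle joint
#: centers, ``HEE``/``TOE``/``MT`` the heel, toe and metatarsal-head
#: skin/shell markers used for the rigid foot triad.
SIDE_MARKERS = ("HJC", "KNE", "ANK", "HEE", "TOE", "MT")
SIDES = ("left", "right")


def marker_label(side: str, name: str) -> str:
    return f"{side[0].upper()}_{name}"


def required_labels() -> list[str]:
    return [marker_label(s, m) for s in SIDES for m in SIDE_MARKERS]


@dataclass
class MarkerTrajectorySet:
    """Frames x labelled 3-D marker positions at a fixed rate.

    ``positions`` has shape (n_frames, n_markers, 3) in meters; ``gaps``
    is a boolean (n_frames, n_markers) array flagging missing samples
    (position values at gap samples are NaN and must not be used).
    """

    rate: float
    labels: list[str]
    positions: np.ndarray
    gaps: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, markers, 3)")
        if len(self.labels) != self.positions.shape[1]:
            raise ValueError("label count does not match position width")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("marker labels must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.gaps is None:
            self.gaps = ~np.isfinite(self.positions).all(axis=2)
        self.gaps = np.asarray(self.gaps, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MissingMarkerError(f"marker {label!r} not present") from None

    def marker(self, label: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one marker."""
        return self.positions[:, self.index(label), :]

    def has(self, label: str) -> bool:
        return label in self.labels

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            self.rate, list(self.labels), self.positions.copy(), self.gaps.copy()
        )


@dataclass
class ForceChannel:
    """Vertical ground-reaction force of one limb, sampled at ``rate``."""

    rate: float
    side: str
    fz: np.ndarray

    def __post_init__(self) -> None:
        self.fz = np.asarray(self.fz, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.isfinite(self.fz).all():
            raise ValueError("force samples must be finite")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.fz.size) / self.rate


@dataclass
class DampingCondition:
    """One swing-phase knee-flexion damping setting.

    ``coefficient`` is the viscous damping coefficient in Nm/(rad/s)
    (resistive torque linearly proportional to flexion angular velocity,
    applied through a one-way clutch during flexion only);
    ``friction_torque`` is a constant Coulomb-style knee friction in Nm.
    """

    label: str = "A"
    coefficient: float = 0.0
    friction_torque: float = 0.05

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise ValueError("damping coefficient must be >= 0")
        if self.friction_torque < 0:
            raise ValueError("friction torque must be >= 0")


@dataclass
class TrialBundle:
    """One walking trial plus everything needed to analyze it."""

    trial: MarkerTrajectorySet
    forces: dict[str, ForceChannel]
    standing: MarkerTrajectorySet
    foot_length: float
    marker_radius: float
    prosthetic_side: str
    condition: DampingCondition = field(default_factory=DampingCondition)

    def __post_init__(self) -> None:
        if self.prosthetic_side not in SIDES:
            raise ValueError("prosthetic side must be 'left' or 'right'")
        if self.standing.n_frames < 1:
            raise ValueError("standing calibration must contain a frame")

    @property
    def sound_side(self) -> str:
        return "right" if self.prosthetic_side == "left" else "left"


@dataclass
class Stride:
    """One swing phase: ipsilateral foot off to next ipsilateral contact."""

    side: str
    foot_off: int
    foot_contact: int
    mid_swing: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.flags

    def duration_s(self, rate: float) -> float:
        return (self.foot_contact - self.foot_off) / rate


@dataclass
class GaitEvents:
    """Detected events for both sides of one trial (kinematic frames)."""

    rate: float
    foot_off: dict[str, list[int]]
    foot_contact: dict[str, list[int]]
    strides: list[Stride]

    def side_strides(self, side: str) -> list[Stride]:
        return [s for s in self.strides if s.side == side]


PERCENT_GRID = np.arange(101)

#: Column order of the per-stride feature table (fixed for file output).
FEATURE_COLUMNS = [
    "stride",
    "condition",
    "coefficient",
    "ell_min_m",
    "tc_min_m",
    "ell_max_t_pct",
    "tc_min_t_pct",
    "ke_max_t_pct",
    "msw_t_pct",
    "ell_max_t_rel_msw_pct",
    "tc_min_t_rel_msw_pct",
    "sts_pct",
    "tzs_hip_m_per_rad",
    "tzs_kne_m_per_rad",
    "tzs_ank_m_per_rad",
    "walking_speed_m_s",
    "hip_height_at_tc_min_m",
    "lateral_hip_ankle_at_tc_min_m",
]


@dataclass
class SwingProfile:
    """Swing-normalized traces on the integer 0..100 %-swing grid."""

    stride: Stride
    grid: np.ndarray
    ell: np.ndarray
    tc: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    tzs_hip: np.ndarray
    tzs_kne: np.ndarray
    tzs_ank: np.ndarray
    msw_pct: float

    def __post_init__(self) -> None:
        for name in ("ell", "tc", "alpha", "beta", "gamma",
                     "tzs_hip", "tzs_kne", "tzs_ank"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"profile trace {name} does not match grid")
            setattr(self, name, arr)


@dataclass
class SwingFeatures:
    """Per-stride scalar outcome set (units in field names)."""

    stride: int
    condition: str
    coefficient: float
    ell_min_m: float
    tc_min_m: float
    ell_max_t_pct: float
    tc_min_t_pct: float
    ke_max_t_pct: float
    msw_t_pct: float
    ell_max_t_rel_msw_pct: float
    tc_min_t_rel_msw_pct: float
    sts_pct: float
    tzs_hip_m_per_rad: float
    tzs_kne_m_per_rad: float
    tzs_ank_m_per_rad: float
    walking_speed_m_s: float = float("nan")
    hip_height_at_tc_min_m: float = float("nan")
    lateral_hip_ankle_at_tc_min_m: float = float("nan")

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS}
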