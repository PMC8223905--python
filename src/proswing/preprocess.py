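"""Marker preprocessing: zero-phase filtering, gap interpolation,
virtual-toe construction from the standing calibration, and rigid-body
tracking of the virtual toe through swing.

The virtual toe (vTOE) estimates the distal endpoint of the prosthetic
foot without a physical marker: heel and toe markers of the standing
calibration are projected onto the floor plane and the landmark is
placed on their connecting axis at the measured foot length (plus a
marker-radius correction) from the projected heel.  During walking it is
reconstructed each frame from the optimal rigid transform of the
heel/toe/metatarsal marker triad, assuming the unloaded foot behaves as
a rigid body.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .containers import MarkerTrajectorySet, marker_label
from .errors import (
    ConfigError,
    DegenerateGeometryError,
    SeriesTooShortError,
    UntrackableSwingError,
)

_PAD_FACTOR = 3  # reflective padding of 3 x order samples per end


def lowpass_filter(series: np.ndarray, rate: float, cutoff: float = 6.0,
                   order: int = 4) -> np.ndarray:
    """Bidirectional (zero-phase) low-pass Butterworth filter.

    Forward-backward application squares the magnitude response and
    cancels the phase; DC gain is exactly 1.  Edges use even-reflective
    padding of ``3 * order`` samples, which alters boundary samples
    relative to an infinite signal.
    """
    if not rate > 2 * cutoff:
        raise ConfigError("sampling rate must exceed twice the cutoff")
    series = np.asarray(series, dtype=float)
    padlen = _PAD_FACTOR * order
    if series.shape[0] <= 3 * padlen:
        raise SeriesTooShortError(
            f"series of {series.shape[0]} samples too short for stable "
            f"edge padding ({3 * padlen} required)")
    b, a = butter(order, cutoff / (rate / 2.0))
    return filtfilt(b, a, series, axis=0, padtype="even", padlen=padlen)


def interpolate_gaps(mset: MarkerTrajectorySet, max_gap: int = 5
                     ) -> MarkerTrajectorySet:
    """Fill marker gaps of at most ``max_gap`` frames by cubic spline.

    Longer gaps are left flagged; interpolation is an explicit caller
    choice, never silent.
    """
    out = mset.copy()
    for j in range(len(out.labels)):
        gaps = out.gaps[:, j]
        if not gaps.any():
            continue
        runs = _gap_runs(gaps)
        valid = ~gaps
        if valid.sum() < 4:
            continue
        t = np.nonzero(valid)[0]
        spline = CubicSpline(t, out.positions[t, j, :], axis=0)
        for start, stop in runs:
            if stop - start <= max_gap and start > 0 and stop < out.n_frames:
                idx = np.arange(start, stop)
                out.positions[idx, j, :] = spline(idx)
                out.gaps[idx, j] = False
    return out


def _gap_runs(gaps: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], gaps.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def filter_trial(mset: MarkerTrajectorySet, cutoff: float = 6.0,
                 order: int = 4) -> MarkerTrajectorySet:
    """Low-pass filter every marker coordinate of a trajectory set."""
    out = mset.copy()
    out.positions = lowpass_filter(out.positions.reshape(out.n_frames, -1),
                                   out.rate, cutoff, order
                                   ).reshape(out.positions.shape)
    return out


@dataclass
class StandingCalibration:
    """Single-frame foot landmarks of the standing calibration."""

    hee: np.ndarray
    toe: np.ndarray
    mt: np.ndarray
    foot_length: float
    marker_radius: float

    def __post_init__(self) -> None:
        if self.foot_length <= 0:
            raise ConfigError("foot_length must be positive")
        self.hee = np.asarray(self.hee, float)
        self.toe = np.asarray(self.toe, float)
        self.mt = np.asarray(self.mt, float)
        if _triad_collinear(np.stack([self.hee, self.toe, self.mt])):
            raise DegenerateGeometryError("HEE/TOE/MT triad is collinear")

    @classmethod
    def from_markers(cls, standing: MarkerTrajectorySet, side: str,
                     foot_length: float, marker_radius: float
                     ) -> "StandingCalibration":
        return cls(
            hee=standing.marker(marker_label(side, "HEE"))[0],
            toe=standing.marker(marker_label(side, "TOE"))[0],
            mt=standing.marker(marker_label(side, "MT"))[0],
            foot_length=foot_length,
            marker_radius=marker_radius,
        )

    @property
    def triad(self) -> np.ndarray:
        return np.stack([self.hee, self.toe, self.mt])


@dataclass
class VirtualToeModel:
    """Virtual toe in the calibration frame plus its foot-triad coordinates."""

    vtoe_calibration: np.ndarray
    local: np.ndarray        # coordinates in the HEE/TOE/MT triad frame
    triad_reference: np.ndarray

    def reconstruct(self, triad: np.ndarray) -> np.ndarray:
        """vTOE position implied by a (possibly moved) marker triad."""
        origin, basis = _triad_frame(triad)
        return origin + basis @ self.local


def _triad_collinear(triad: np.ndarray, tol: float = 1e-9) -> bool:
    a = triad[1] - triad[0]
    b = triad[2] - triad[0]
    return float(np.linalg.norm(np.cross(a, b))) <= tol * max(
        np.linalg.norm(a) * np.linalg.norm(b), 1e-30)


def _triad_frame(triad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame carried by three markers (origin at the heel)."""
    if _triad_collinear(triad):
        raise DegenerateGeometryError("degenerate marker triad")
    origin = triad[0]
    e1 = triad[1] - origin
    e1 = e1 / np.linalg.norm(e1)
    v = triad[2] - origin
    e2 = v - (v @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return origin, np.stack([e1, e2, e3], axis=1)


def build_virtual_toe(calib: StandingCalibration,
                      radius_sign: int = 1) -> VirtualToeModel:
    """Place the virtual toe from the standing calibration.

    Heel and toe markers are projected onto the floor plane (z := 0);
    the landmark lies on the projected heel-to-toe axis at
    ``foot_length + radius_sign * marker_radius`` from the projected
    heel.  The default ``radius_sign=+1`` treats the heel-marker center
    as one radius posterior of the heel surface; the sign is
    configurable because the correction convention is a modelling
    choice.
    """
    if radius_sign not in (-1, 0, 1):
        raise ConfigError("radius_sign must be -1, 0 or +1")
    heel_floor = np.array([calib.hee[0], calib.hee[1], 0.0])
    toe_floor = np.array([calib.toe[0], calib.toe[1], 0.0])
    axis = toe_floor - heel_floor
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "projected heel and toe markers coincide")
    axis /= norm
    vtoe = heel_floor + (calib.foot_length
                         + radius_sign * calib.marker_radius) * axis
    origin, basis = _triad_frame(calib.triad)
    local = basis.T @ (vtoe - origin)
    model = VirtualToeModel(vtoe_calibration=vtoe, local=local,
                            triad_reference=calib.triad.copy())
    assert np.linalg.norm(model.reconstruct(calib.triad) - vtoe) <= 1e-12
    return model


def rigid_transform(reference: np.ndarray, current: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares optimal proper rigid transform reference -> current.

    Kabsch/Umeyama solution: returns (R, t) with R orthonormal,
    det(R) = +1, minimizing the summed squared marker residuals.
    """
    P = np.asarray(reference, float)
    Q = np.asarray(current, float)
    if _triad_collinear(P) or _triad_collinear(Q):
        raise DegenerateGeometryError("collinear triad; rotation ill-defined")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def track_virtual_toe(
    trial: MarkerTrajectorySet,
    side: str,
    model: VirtualToeModel,
    windows: list[tuple[int, int]] | None = None,
    max_gap_fraction: float = 0.10,
) -> np.ndarray:
    """Reconstruct the virtual toe per frame from the foot marker triad.

    ``windows`` are inclusive (start, stop) frame ranges (the swing
    phases); with ``None`` the full trial is tracked.  Within a window,
    gap frames are linearly interpolated if they make up at most
    ``max_gap_fraction`` of the window, otherwise the swing is declared
    untrackable.  Returns an (n_frames, 3) array, NaN outside windows.
    """
    labels = [marker_label(side, m) for m in ("HEE", "TOE", "MT")]
    idx = [trial.index(label) for label in labels]
    pos = trial.positions[:, idx, :].copy()
    gaps = trial.gaps[:, idx].any(axis=1)
    if windows is None:
        windows = [(0, trial.n_frames - 1)]
    out = np.full((trial.n_frames, 3), np.nan)
    for start, stop in windows:
        frames = np.arange(start, stop + 1)
        g = gaps[frames]
        if g.mean() > max_gap_fraction:
            raise UntrackableSwingError(
                f"untrackable swing [{start}, {stop}]: "
                f"{100 * g.mean():.0f}% gap frames")
        if g.any():
            valid = frames[~g]
            for j in range(3):
                for k in range(3):
                    pos[frames, j, k] = np.interp(frames, valid,
                                                  pos[valid, j, k])
        for f in frames:
            R, t = rigid_transform(model.triad_reference, pos[f])
            out[f] = R @ model.vtoe_calibration + t
    return out
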