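"""Gait event detection: kinetic foot off, kinematic foot contact,
stride pairing, and the mid-swing event.

Foot off is the first kinetic sample strictly below a vertical force
threshold (default 5 N) after at least 50 ms continuously at/above it
(the debounce rejects noise-triggered events); the kinetic sample is
mapped to the nearest kinematic frame with ties toward the earlier
frame.  Foot contact is kinematic: a candidate at each local maximum of
the ankle's anterior position relative to the mid-hip point, confirmed
at the first subsequent frame where the ankle center returns to
standing height within a tolerance with a small vertical velocity.
Strides whose contact cannot be confirmed are flagged, not guessed, and
excluded from feature averaging downstream.  Mid-swing is the frame at
which the swing-limb ankle passes the stance-limb ankle along the
walking direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .containers import (
    ForceChannel,
    GaitEvents,
    MarkerTrajectorySet,
    Stride,
    marker_label,
)
from .errors import ConfigError, ProswingError


@dataclass
class EventParams:
    """Detection thresholds (units in field names)."""

    force_threshold_n: float = 5.0
    debounce_s: float = 0.05
    height_tol_m: float = 0.010
    vz_threshold_m_s: float = 0.05
    contact_search_s: float = 0.5
    peak_prominence_m: float = 0.05
    snap_direction: bool = True
    min_swing_s: float = 0.1


def kinetic_to_frame(sample: int, ratio: int) -> int:
    """Nearest kinematic frame for a kinetic sample; ties toward earlier."""
    return int(np.ceil(sample / ratio - 0.5))


def detect_foot_off(force: ForceChannel, kinematic_rate: float,
                    threshold: float = 5.0, debounce_s: float = 0.05
                    ) -> list[int]:
    """Foot-off frames from a vertical force channel.

    Event at the first kinetic sample strictly below ``threshold``
    following at least ``debounce_s`` continuously at/above it.  An
    absent crossing yields an empty list (not an error).
    """
    ratio = force.rate / kinematic_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigError("force rate must be an integer multiple of the "
                          "kinematic rate")
    ratio = int(round(ratio))
    need = int(np.ceil(debounce_s * force.rate))
    above = force.fz >= threshold
    events = []
    run = 0
    for j, a in enumerate(above):
        if a:
            run += 1
        else:
            if run >= need:
                events.append(kinetic_to_frame(j, ratio))
            run = 0
    return events


def walking_direction(hip_left: np.ndarray, hip_right: np.ndarray,
                      snap: bool = True, min_displacement: float = 0.5
                      ) -> np.ndarray:
    """Unit walking-direction vector in the floor plane.

    Net displacement of the mid-hip point, floor-projected and
    normalized; optionally snapped to the nearest lab axis (+-x or +-y),
    matching a capture volume aligned with the walkway.
    """
    mid = 0.5 * (np.asarray(hip_left, float) + np.asarray(hip_right, float))
    disp = mid[-1] - mid[0]
    disp[2] = 0.0
    norm = np.linalg.norm(disp)
    if norm <= min_displacement:
        raise ProswingError(
            f"net pelvis displacement {norm:.2f} m too small to define a "
            "walking direction")
    d = disp / norm
    if snap:
        axis = int(np.argmax(np.abs(d[:2])))
        snapped = np.zeros(3)
        snapped[axis] = np.sign(d[axis])
        return snapped
    return d


def _vertical_velocity(z: np.ndarray, rate: float) -> np.ndarray:
    return np.gradient(z, 1.0 / rate)


def detect_foot_contact(
    ankle: np.ndarray,
    midhip: np.ndarray,
    standing_ankle_height: float,
    direction: np.ndarray,
    rate: float,
    params: EventParams | None = None,
) -> tuple[list[int], list[int]]:
    """Foot-contact frames from the (filtered) ankle-center trajectory.

    Returns ``(contacts, uncertain_candidates)``: for each anterior-peak
    candidate without a confirming frame (height within tolerance of
    standing and low vertical speed) inside the search window, the
    candidate frame is reported as uncertain instead of an event.
    """
    params = params or EventParams()
    anterior = (np.asarray(ankle) - np.asarray(midhip)) @ np.asarray(direction)
    peaks, _ = find_peaks(anterior, prominence=params.peak_prominence_m)
    z = np.asarray(ankle)[:, 2]
    vz = _vertical_velocity(z, rate)
    ok = (np.abs(z - standing_ankle_height) <= params.height_tol_m) \
        & (np.abs(vz) < params.vz_threshold_m_s)
    horizon = int(round(params.contact_search_s * rate))
    contacts, uncertain = [], []
    for p in peaks:
        window = ok[p: p + horizon + 1]
        hits = np.flatnonzero(window)
        if hits.size:
            contacts.append(int(p + hits[0]))
        else:
            uncertain.append(int(p))
    return contacts, uncertain


def detect_mid_swing(
    swing_ankle: np.ndarray,
    stance_ankle: np.ndarray,
    direction: np.ndarray,
    window: tuple[int, int],
) -> tuple[int, bool]:
    """Mid-swing frame: swing ankle passes the stance ankle.

    Minimizes the absolute along-direction ankle separation within the
    stride window (ties toward the earlier frame).  Returns
    ``(frame, flagged)``; flagged when the separation never changes
    sign (the swing ankle never passes).
    """
    i0, i1 = window
    if not i1 > i0:
        raise ProswingError("invalid stride window")
    delta = ((np.asarray(swing_ankle) - np.asarray(stance_ankle))
             @ np.asarray(direction))[i0: i1 + 1]
    frame = i0 + int(np.argmin(np.abs(delta)))
    flagged = not (np.any(delta < 0) and np.any(delta > 0))
    return frame, flagged


def detect_events(
    trial: MarkerTrajectorySet,
    forces: dict[str, ForceChannel],
    standing: MarkerTrajectorySet,
    params: EventParams | None = None,
) -> GaitEvents:
    """Full event detection for both sides of one (filtered) trial."""
    params = params or EventParams()
    direction = walking_direction(trial.marker("L_HJC"), trial.marker("R_HJC"),
                                  snap=params.snap_direction)
    midhip = 0.5 * (trial.marker("L_HJC") + trial.marker("R_HJC"))
    foot_off: dict[str, list[int]] = {}
    foot_contact: dict[str, list[int]] = {}
    uncertain: dict[str, list[int]] = {}
    for side in ("left", "right"):
        if side not in forces:
            raise ProswingError(f"no force channel for side {side!r}; "
                                "foot off unavailable")
        foot_off[side] = detect_foot_off(
            forces[side], trial.rate, params.force_threshold_n,
            params.debounce_s)
        ankle = trial.marker(marker_label(side, "ANK"))
        h_stand = float(standing.marker(marker_label(side, "ANK"))[0, 2])
        foot_contact[side], uncertain[side] = detect_foot_contact(
            ankle, midhip, h_stand, direction, trial.rate, params)

    min_gap = int(round(params.min_swing_s * trial.rate))
    strides: list[Stride] = []
    for side in ("left", "right"):
        other = "right" if side == "left" else "left"
        swing_ankle = trial.marker(marker_label(side, "ANK"))
        stance_ankle = trial.marker(marker_label(other, "ANK"))
        for off in foot_off[side]:
            contact = next((c for c in foot_contact[side]
                            if c >= off + min_gap), None)
            flags = []
            if contact is None:
                cand = next((c for c in uncertain[side]
                             if c >= off + min_gap), None)
                if cand is None:
                    continue
                contact = cand
                flags.append("uncertain_contact")
            msw, msw_flag = detect_mid_swing(swing_ankle, stance_ankle,
                                             direction, (off, contact))
            if msw_flag:
                flags.append("no_mid_swing_crossing")
            if not off < msw < contact:
                flags.append("event_order")
            strides.append(Stride(side=side, foot_off=off,
                                  foot_contact=contact, mid_swing=msw,
                                  flags=flags))
    strides.sort(key=lambda s: s.foot_off)
    return GaitEvents(rate=trial.rate, foot_off=foot_off,
                      foot_contact=foot_contact, strides=strides)
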