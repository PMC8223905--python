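"""End-to-end orchestration: filter -> virtual toe -> events -> profiles
-> features -> condition averaging -> trends.

This module glues the processing stages together for library users, the
command-line interface and the test-suite; each stage remains usable on
its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics, trends
from .containers import (
    DampingCondition,
    FEATURE_COLUMNS,
    GaitEvents,
    Stride,
    SwingFeatures,
    SwingProfile,
    TrialBundle,
    marker_label,
)
from .errors import ProswingError
from .events import EventParams, detect_events, walking_direction
from .preprocess import (
    StandingCalibration,
    build_virtual_toe,
    filter_trial,
    interpolate_gaps,
    track_virtual_toe,
)
from .simulate import SimConfig, default_sweep_conditions, sweep_damping

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Everything tunable about the analysis, with logged defaults."""

    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    events: EventParams = field(default_factory=EventParams)
    radius_sign: int = 1
    gap_limit_frames: int = 5
    strides_per_condition: int = 5
    ell_sagittal: bool = False

    def log_decisions(self) -> None:
        log.info("filter: %g Hz, order %d, bidirectional", self.filter_cutoff_hz,
                 self.filter_order)
        log.info("virtual-toe marker-radius sign: %+d", self.radius_sign)
        log.info("event thresholds: force %g N, debounce %g s, height tol %g m,"
                 " vz %g m/s", self.events.force_threshold_n,
                 self.events.debounce_s, self.events.height_tol_m,
                 self.events.vz_threshold_m_s)
        log.info("argmin/argmax ties break toward the earlier frame")


@dataclass
class AnalysisResult:
    """Outputs of one analyzed trial."""

    bundle: TrialBundle
    direction: np.ndarray
    events: GaitEvents
    profiles: list[SwingProfile]
    features: list[SwingFeatures]
    flagged: list[Stride]
    vtoe: np.ndarray

    @property
    def features_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.as_row() for f in self.features],
                            columns=FEATURE_COLUMNS)


def analyze_bundle(bundle: TrialBundle,
                   params: PipelineParams | None = None) -> AnalysisResult:
    """Run the full analysis on one trial bundle."""
    params = params or PipelineParams()
    params.log_decisions()
    pros, sound = bundle.prosthetic_side, bundle.sound_side
    rate = bundle.trial.rate

    filtered = filter_trial(interpolate_gaps(bundle.trial,
                                             params.gap_limit_frames),
                            params.filter_cutoff_hz, params.filter_order)
    events = detect_events(filtered, bundle.forces, bundle.standing,
                           params.events)
    direction = walking_direction(filtered.marker("L_HJC"),
                                  filtered.marker("R_HJC"),
                                  snap=params.events.snap_direction)

    calib = StandingCalibration.from_markers(
        bundle.standing, pros, bundle.foot_length, bundle.marker_radius)
    model = build_virtual_toe(calib, params.radius_sign)
    pros_strides = events.side_strides(pros)
    accepted = [s for s in pros_strides if s.accepted]
    flagged = [s for s in events.strides if not s.accepted]
    for s in flagged:
        log.info("flagged %s stride at frame %d: %s", s.side, s.foot_off,
                 s.flags)
    windows = [(s.foot_off, s.foot_contact) for s in accepted]
    vtoe = track_virtual_toe(filtered, pros, model, windows)

    standing_dir = direction  # standing frame shares the lab axes
    foot_offset = metrics.standing_foot_shank_offset(
        bundle.standing.marker(marker_label(pros, "KNE"))[0],
        bundle.standing.marker(marker_label(pros, "ANK"))[0],
        bundle.standing.marker(marker_label(pros, "TOE"))[0],
        standing_dir)

    hip = filtered.marker(marker_label(pros, "HJC"))
    knee = filtered.marker(marker_label(pros, "KNE"))
    ankle = filtered.marker(marker_label(pros, "ANK"))
    toe = filtered.marker(marker_label(pros, "TOE"))
    midhip = 0.5 * (filtered.marker("L_HJC") + filtered.marker("R_HJC"))
    speed = metrics.walking_speed(midhip, direction, rate)

    sound_strides = [s for s in events.side_strides(sound) if s.accepted]
    sound_mid = np.array([0.5 * (s.foot_off + s.foot_contact)
                          for s in sound_strides], dtype=float)

    profiles, feats = [], []
    for k, s in enumerate(accepted):
        idx = np.arange(s.foot_off, s.foot_contact + 1)
        tt = idx / rate
        profile = metrics.swing_profile_from_traces(
            t=tt, hip=hip[idx], knee=knee[idx], ankle=ankle[idx],
            vtoe=vtoe[idx], direction=direction,
            t_off=s.foot_off / rate, t_contact=s.foot_contact / rate,
            t_msw=s.mid_swing / rate, toe=toe[idx],
            standing_foot_offset=foot_offset, stride=s)
        if params.ell_sagittal:
            profile.ell = np.interp(
                profile.grid,
                100 * (tt - tt[0]) / (tt[-1] - tt[0]),
                metrics.compute_ell_sagittal(hip[idx], vtoe[idx], direction))
        if sound_mid.size:
            mid = 0.5 * (s.foot_off + s.foot_contact)
            j = int(np.argmin(np.abs(sound_mid - mid)))
            sts = metrics.swing_time_symmetry(
                s.duration_s(rate), sound_strides[j].duration_s(rate))
        else:
            sts = float("nan")
        f = metrics.extract_features(
            profile, stride_id=k, condition=bundle.condition.label,
            coefficient=bundle.condition.coefficient, sts_pct=sts)
        i_tc = s.foot_off + int(round(f.tc_min_t_pct / 100
                                      * (s.foot_contact - s.foot_off)))
        if not 0 <= i_tc < filtered.n_frames:
            raise ProswingError("minimum-toe-clearance frame outside trial")
        f.walking_speed_m_s = speed
        f.hip_height_at_tc_min_m = float(hip[i_tc, 2])
        f.lateral_hip_ankle_at_tc_min_m = float(abs(hip[i_tc, 1]
                                                    - ankle[i_tc, 1]))
        profiles.append(profile)
        feats.append(f)
    return AnalysisResult(bundle=bundle, direction=direction, events=events,
                          profiles=profiles, features=feats, flagged=flagged,
                          vtoe=vtoe)


@dataclass
class SweepResult:
    """One simulated participant analyzed across a damping sweep."""

    participant: str
    outputs: list            # SimOutput per condition
    analyses: list[AnalysisResult]
    summaries: list[trends.ConditionSummary]
    fits: dict[str, trends.TrendFit]
    report: trends.TrendReport
    directions: pd.DataFrame

    @property
    def features_frame(self) -> pd.DataFrame:
        return pd.concat([a.features_frame for a in self.analyses],
                         ignore_index=True)


def run_sweep(
    config: SimConfig,
    conditions: list[DampingCondition] | None = None,
    params: PipelineParams | None = None,
    participant: str = "S1",
) -> SweepResult:
    """Simulate + analyze a full damping sweep for one synthetic participant."""
    params = params or PipelineParams()
    conditions = conditions or default_sweep_conditions()
    outputs = sweep_damping(config, conditions)
    analyses, summaries = [], []
    for out in outputs:
        res = analyze_bundle(out.bundle, params)
        analyses.append(res)
        means = trends.average_strides(
            res.features, params.strides_per_condition,
            flagged=[str(s.flags) for s in res.flagged])
        summaries.append(trends.ConditionSummary(
            participant=participant, condition=out.config.damping,
            means=means, stride_count=params.strides_per_condition))
    fits = trends.fit_trends(summaries)
    report = trends.aggregate_report({participant: fits})
    directions = trends.check_trend_directions(summaries)
    return SweepResult(participant=participant, outputs=outputs,
                       analyses=analyses, summaries=summaries, fits=fits,
                       report=report, directions=directions)


def summaries_from_features(features_df: pd.DataFrame, participant: str,
                            n: int = 5) -> list[trends.ConditionSummary]:
    """Rebuild condition summaries from a concatenated feature table."""
    out = []
    for (label, coef), grp in features_df.groupby(["condition", "coefficient"],
                                                  sort=True):
        if len(grp) < n:
            raise ProswingError(
                f"condition {label!r}: {len(grp)} strides < required {n}")
        rows = grp.sort_values("stride").head(n)
        means = {v: float(rows[v].mean()) for v in trends.TREND_VARIABLES}
        out.append(trends.ConditionSummary(
            participant=participant,
            condition=DampingCondition(str(label), float(coef), 0.0),
            means=means, stride_count=n))
    return sorted(out, key=lambda s: s.condition.coefficient)


def sim_config_from_dict(d: dict) -> tuple[SimConfig, list[DampingCondition]]:
    """Build a SimConfig (and optional sweep conditions) from plain keys."""
    d = dict(d or {})
    conds = []
    for c in d.pop("conditions", []):
        conds.append(DampingCondition(
            label=str(c.get("label", "?")),
            coefficient=float(c.get("coefficient", 0.0)),
            friction_torque=float(c.get("friction_torque", 0.05))))
    damping = d.pop("damping", None)
    cfg = SimConfig(**d)
    if damping:
        cfg = replace(cfg, damping=DampingCondition(
            label=str(damping.get("label", "A")),
            coefficient=float(damping.get("coefficient", 0.0)),
            friction_torque=float(damping.get("friction_torque", 0.05))))
    return cfg, conds
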