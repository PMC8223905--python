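"""Condition averaging, damping-trend regression and direction checks.

For each participant, per-stride features are averaged over a fixed
number of accepted strides per damping condition; each variable is then
regressed on the damping coefficient with linear and quadratic ordinary
least squares, and the goodness-of-fit (R^2) is averaged across
participants.  A qualitative direction check verifies that condition
means move the way increased swing-phase knee flexion damping is
expected to move them (reduced toe clearance, more extended minimum leg
length, earlier key-event timings, swing-time symmetry approaching 50%,
reduced sensitivity of toe height to hip rotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import DampingCondition, SwingFeatures
from .errors import InsufficientStridesError, ProswingError

log = logging.getLogger(__name__)

#: Feature fields entering the trend analysis.
TREND_VARIABLES = [
    "ell_min_m",
    "tc_min_m",
    "ell_max_t_pct",
    "tc_min_t_pct",
    "ke_max_t_pct",
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

#: Expected sign of each variable's association with increasing damping.
EXPECTED_DIRECTIONS = {
    "tc_min_m": -1,            # reduced toe clearance
    "ell_min_m": +1,           # more extended limb at its shortest
    "tc_min_t_pct": -1,        # minimum clearance earlier in swing
    "ell_max_t_pct": -1,       # peak leg length earlier in swing
    "ke_max_t_pct": -1,        # knee extension earlier in swing
    "sts_pct": -1,             # shorter prosthetic swing, toward 50%
    "tzs_hip_m_per_rad": -1,   # toe height less sensitive to hip rotation
}


@dataclass
class ConditionSummary:
    """Per-variable stride means of one participant x damping condition."""

    participant: str
    condition: DampingCondition
    means: dict[str, float]
    stride_count: int


@dataclass
class TrendFit:
    """Linear and quadratic least-squares fits of one variable vs damping."""

    variable: str
    linear_coef: tuple[float, float]            # (intercept, slope)
    r2_linear: float
    quadratic_coef: tuple[float, float, float]  # (intercept, linear, quad)
    r2_quadratic: float
    n: int


@dataclass
class TrendReport:
    """Per-participant fits plus cross-participant mean R^2 per variable."""

    fits: dict[str, dict[str, TrendFit]]        # participant -> variable -> fit
    mean_r2: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def average_strides(features: list[SwingFeatures], n: int = 5,
                    flagged: list[str] | None = None) -> dict[str, float]:
    """Arithmetic mean of each feature over the first n accepted strides."""
    if len(features) < n:
        raise InsufficientStridesError(
            f"need {n} accepted strides, have {len(features)}"
            + (f"; flagged: {flagged}" if flagged else ""))
    rows = pd.DataFrame([f.as_row() for f in features[:n]])
    return {v: float(rows[v].mean()) for v in TREND_VARIABLES}


def _ols_r2(x: np.ndarray, y: np.ndarray, degree: int
            ) -> tuple[np.ndarray, float]:
    X = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        log.info("constant variable: R^2 defined as 1 by convention")
        return coef, 1.0
    return coef, 1.0 - float(np.sum(resid**2)) / sst


def fit_trends(summaries: list[ConditionSummary]) -> dict[str, TrendFit]:
    """Per-variable linear and quadratic OLS against the damping coefficient."""
    x = np.array([s.condition.coefficient for s in summaries], dtype=float)
    if np.unique(x).size < 3:
        raise ProswingError("need at least 3 distinct damping coefficients")
    fits: dict[str, TrendFit] = {}
    for var in TREND_VARIABLES:
        y = np.array([s.means[var] for s in summaries], dtype=float)
        lin, r2_lin = _ols_r2(x, y, 1)
        quad, r2_quad = _ols_r2(x, y, 2)
        fits[var] = TrendFit(
            variable=var,
            linear_coef=(float(lin[0]), float(lin[1])),
            r2_linear=r2_lin,
            quadratic_coef=(float(quad[0]), float(quad[1]), float(quad[2])),
            r2_quadratic=r2_quad,
            n=len(summaries),
        )
    return fits


def aggregate_report(fits_by_participant: dict[str, dict[str, TrendFit]]
                     ) -> TrendReport:
    """Unweighted mean R^2 per variable and model across participants."""
    if not fits_by_participant:
        raise ProswingError("need at least one participant")
    rows = []
    for var in TREND_VARIABLES:
        r2_lin, r2_quad = [], []
        for pid, fits in fits_by_participant.items():
            if var not in fits:
                raise ProswingError(
                    f"variable {var!r} missing for participant {pid!r}")
            r2_lin.append(fits[var].r2_linear)
            r2_quad.append(fits[var].r2_quadratic)
        rows.append({"variable": var,
                     "mean_r2_linear": float(np.mean(r2_lin)),
                     "mean_r2_quadratic": float(np.mean(r2_quad))})
    return TrendReport(fits=dict(fits_by_participant),
                       mean_r2=pd.DataFrame(rows))


def check_trend_directions(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Pass/fail table of expected trend directions with rising damping.

    Direction is the Spearman sign of association between condition
    means and damping coefficients (for two conditions this reduces to
    the sign of the difference).
    """
    if len(summaries) < 2:
        raise ProswingError("need at least 2 conditions")
    order = sorted(summaries, key=lambda s: s.condition.coefficient)
    x = np.array([s.condition.coefficient for s in order])
    rows = []
    for var, expected in EXPECTED_DIRECTIONS.items():
        y = np.array([s.means[var] for s in order])
        if len(order) == 2 or np.unique(y).size == 1:
            rho = float(np.sign(y[-1] - y[0]))
        else:
            rho = float(spearmanr(x, y).statistic)
        observed = int(np.sign(rho)) if rho != 0 else 0
        rows.append({"variable": var, "expected_sign": expected,
                     "spearman_rho": rho, "observed_sign": observed,
                     "passed": observed == expected})
    return pd.DataFrame(rows)
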