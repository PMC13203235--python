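"""Per-patient variability statistics.

All metrics accept either a :class:`~troughvar.data.TroughTrajectory` or a
bare sequence of positive concentrations.  Minimum length is 2 for every
metric; the inclusion threshold (default 3 measurements) is applied upstream
by :func:`troughvar.data.filter_min_measurements`, keeping this module
threshold-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Cohort, TroughTrajectory
from .errors import InsufficientDataError
from .zones import DEFAULT_HIGH, DEFAULT_LOW, count_zone_changes, zone_sequence

DEFAULT_STABILITY_THRESHOLD = 20.0  # CV% below this => "stable" patient


def _values(traj) -> np.ndarray:
    if isinstance(traj, TroughTrajectory):
        return np.asarray(traj.concentrations, dtype=float)
    return np.asarray(traj, dtype=float)


def _require(values: np.ndarray, op: str) -> None:
    if values.size < 2:
        raise InsufficientDataError(
            f"{op} requires at least 2 measurements, got {values.size}"
        )


def cv_percent(traj, ddof: int = 1) -> float:
    """Coefficient of variation: 100 * SD / mean.

    Uses the sample standard deviation (``ddof=1``) by default; pass
    ``ddof=0`` for the population SD as a sensitivity variant.
    """
    v = _values(traj)
    _require(v, "cv_percent")
    return 100.0 * float(np.std(v, ddof=ddof)) / float(np.mean(v))


def swing_index(traj) -> float:
    """(Cmax - Cmin) / Cmean — relative peak-to-trough amplitude."""
    v = _values(traj)
    _require(v, "swing_index")
    return float((v.max() - v.min()) / v.mean())


def mssd(traj) -> float:
    """Mean ABSOLUTE successive difference: (1/(n-1)) * sum |C[i+1] - C[i]|.

    Order-sensitive.  Note this follows the absolute-difference definition,
    not the classical mean *squared* successive difference — see
    :func:`mean_squared_successive_difference` for that variant.
    """
    v = _values(traj)
    _require(v, "mssd")
    return float(np.mean(np.abs(np.diff(v))))


def mean_squared_successive_difference(traj) -> float:
    """Classical von-Neumann mean squared successive difference (variant only).

    Exposed under a distinct name; never used by the default analysis.
    """
    v = _values(traj)
    _require(v, "mean_squared_successive_difference")
    return float(np.mean(np.diff(v) ** 2))


def trough_range(traj) -> float:
    v = _values(traj)
    _require(v, "trough_range")
    return float(v.max() - v.min())


def stability_flag(cv_pct: float, threshold: float = DEFAULT_STABILITY_THRESHOLD) -> bool:
    """True iff CV% is strictly below the stability threshold."""
    return cv_pct < threshold


@dataclass(frozen=True)
class VariabilityProfile:
    """The per-patient variability metric vector."""

    patient_id: str
    cohort: str
    n_measurements: int
    mean_trough: float
    min_trough: float
    max_trough: float
    cv_pct: float
    swing_index: float
    mssd: float
    trough_range: float
    n_zone_changes: int
    stable: bool


def profile_trajectory(
    traj: TroughTrajectory,
    *,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
    zone_low: float = DEFAULT_LOW,
    zone_high: float = DEFAULT_HIGH,
    ddof: int = 1,
) -> VariabilityProfile:
    v = _values(traj)
    try:
        _require(v, "profile")
        cv = cv_percent(v, ddof=ddof)
        zs = zone_sequence(traj, zone_low, zone_high)
        return VariabilityProfile(
            patient_id=traj.patient_id,
            cohort=traj.cohort,
            n_measurements=int(v.size),
            mean_trough=float(v.mean()),
            min_trough=float(v.min()),
            max_trough=float(v.max()),
            cv_pct=cv,
            swing_index=swing_index(v),
            mssd=mssd(v),
            trough_range=trough_range(v),
            n_zone_changes=count_zone_changes(zs),
            stable=stability_flag(cv, stability_threshold),
        )
    except InsufficientDataError as exc:
        raise InsufficientDataError(f"patient {traj.patient_id!r}: {exc}") from exc


def profile_cohort(
    cohort: Cohort,
    *,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
    zone_low: float = DEFAULT_LOW,
    zone_high: float = DEFAULT_HIGH,
    ddof: int = 1,
) -> list[VariabilityProfile]:
    """One profile per trajectory; insufficient-data errors name the patient."""
    return [
        profile_trajectory(
            t,
            stability_threshold=stability_threshold,
            zone_low=zone_low,
            zone_high=zone_high,
            ddof=ddof,
        )
        for t in cohort.trajectories
    ]


SUMMARY_METRICS = (
    "cv_pct",
    "swing_index",
    "mssd",
    "trough_range",
    "n_zone_changes",
    "mean_trough",
)


@dataclass(frozen=True)
class MetricSummary:
    median: float
    q1: float
    q3: float


def summarize_profiles(
    profiles: Iterable[VariabilityProfile],
    metrics: Sequence[str] = SUMMARY_METRICS,
) -> dict[str, MetricSummary]:
    """Median and IQR per metric, 25th/75th percentiles by linear interpolation."""
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("cannot summarize an empty profile collection")
    out = {}
    for m in metrics:
        vals = np.asarray([getattr(p, m) for p in profiles], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        out[m] = MetricSummary(median=float(med), q1=float(q1), q3=float(q3))
    return out


def profiles_to_frame(profiles: Iterable[VariabilityProfile]) -> pd.DataFrame:
    """Tidy per-patient metrics table for CSV export."""
    rows = []
    for p in profiles:
        d = asdict(p)
        d["stable"] = int(d["stable"])
        rows.append(d)
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "patient_id",
            "cohort",
            "n_measurements",
            "mean_trough",
            "min_trough",
            "max_trough",
            "cv_pct",
            "swing_index",
            "mssd",
            "trough_range",
            "n_zone_changes",
            "stable",
        ],
    )
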