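"""Three-zone trough classification and pooled first-order transition matrices.

Two distinct transition notions coexist and are deliberately named apart:

* ``count_zone_changes`` — per-patient count of consecutive pairs whose zones
  DIFFER (persistence pairs not counted); this is the per-patient
  "zone transitions" summary metric.
* ``pooled_transition_matrix`` — cohort-level 3x3 matrix over ALL consecutive
  within-patient pairs, persistence included, so its total equals
  measurements minus patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Cohort, TroughTrajectory
from .errors import ConfigurationError, EmptyCohortError, InsufficientDataError

DEFAULT_LOW = 15.0
DEFAULT_HIGH = 20.0


class Zone(Enum):
    """Therapeutic zone of a single trough value; ordered sub < target < supra."""

    SUBTHERAPEUTIC = 0
    TARGET = 1
    SUPRATHERAPEUTIC = 2

    @property
    def label(self) -> str:
        return _LABELS[self]

    def __lt__(self, other: "Zone") -> bool:
        return self.value < other.value


_LABELS = {
    Zone.SUBTHERAPEUTIC: "subtherapeutic",
    Zone.TARGET: "target",
    Zone.SUPRATHERAPEUTIC: "supratherapeutic",
}

ZONES = (Zone.SUBTHERAPEUTIC, Zone.TARGET, Zone.SUPRATHERAPEUTIC)
ZONE_LABELS = tuple(z.label for z in ZONES)


def classify_zone(
    concentration: float, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> Zone:
    """Classify a trough concentration; band boundaries belong to the target zone."""
    if low >= high:
        raise ConfigurationError(f"target band requires low < high, got {low} >= {high}")
    if concentration <= 0:
        raise ConfigurationError(f"concentration must be positive, got {concentration}")
    if concentration < low:
        return Zone.SUBTHERAPEUTIC
    if concentration > high:
        return Zone.SUPRATHERAPEUTIC
    return Zone.TARGET


@dataclass(frozen=True)
class ZoneSequence:
    patient_id: str
    zones: tuple[Zone, ...]


def zone_sequence(
    traj: TroughTrajectory, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> ZoneSequence:
    return ZoneSequence(
        patient_id=traj.patient_id,
        zones=tuple(classify_zone(c, low, high) for c in traj.concentrations),
    )


def count_zone_changes(zs: ZoneSequence | tuple[Zone, ...]) -> int:
    """Number of consecutive pairs whose zones differ (persistence not counted)."""
    zones = zs.zones if isinstance(zs, ZoneSequence) else tuple(zs)
    if len(zones) < 2:
        raise InsufficientDataError(
            "zone-change counting requires at least two measurements"
        )
    return sum(a != b for a, b in zip(zones[:-1], zones[1:]))


@dataclass(frozen=True)
class TransitionMatrix:
    """3x3 zone-transition counts (row = preceding zone, column = following).

    Rows never observed as a departure zone have zero counts and carry
    undefined (NaN) probabilities — they are neither zeroed nor imputed.
    """

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ConfigurationError("counts must be a 3x3 nonnegative array")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def row_observed(self) -> np.ndarray:
        """Boolean per row: at least one departure observed from that zone."""
        return self.counts.sum(axis=1) > 0

    @property
    def probabilities(self) -> np.ndarray:
        """Row-conditional probabilities; NaN for rows with no departures."""
        row_sums = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = self.counts / row_sums[:, None]
        probs[row_sums == 0] = np.nan
        return probs

    def to_dict(self) -> dict:
        probs = self.probabilities
        return {
            "zones": list(ZONE_LABELS),
            "counts": self.counts.tolist(),
            "probabilities": [
                [None if np.isnan(p) else float(p) for p in row] for row in probs
            ],
            "row_observed": [bool(b) for b in self.row_observed],
            "n_transitions": self.n_transitions,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=ZONE_LABELS, columns=ZONE_LABELS)


def markov_pairs(
    traj: TroughTrajectory, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> list[tuple[Zone, Zone]]:
    """All consecutive zone pairs of one trajectory, persistence included."""
    zones = zone_sequence(traj, low, high).zones
    return list(zip(zones[:-1], zones[1:]))


def pooled_transition_matrix(
    cohort: Cohort, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> TransitionMatrix:
    """Pool all within-patient consecutive zone pairs of a cohort.

    No pair spans two patients; each trajectory of length L contributes
    exactly L - 1 pairs, so the total equals measurements - patients.
    Patients with longer trajectories therefore contribute proportionally
    more transitions (no patient weighting).
    """
    if cohort.n_patients == 0:
        raise EmptyCohortError(f"cohort {cohort.label!r} has no trajectories")
    counts = np.zeros((3, 3), dtype=int)
    for traj in cohort.trajectories:
        for a, b in markov_pairs(traj, low, high):
            counts[a.value, b.value] += 1
    return TransitionMatrix(counts)


def patient_weighted_transition_matrix(
    cohort: Cohort, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> tuple[np.ndarray, np.ndarray]:
    """Opt-in extension: average of per-patient row-conditional matrices.

    Each row of the result averages the per-patient probability rows over
    patients with at least one observed departure from that row's zone.
    This weighting is NOT part of the default analysis and is provided for
    methodological exploration only.

    Returns ``(probabilities, n_patients_per_row)``.
    """
    if cohort.n_patients == 0:
        raise EmptyCohortError(f"cohort {cohort.label!r} has no trajectories")
    acc = np.zeros((3, 3))
    n_per_row = np.zeros(3, dtype=int)
    for traj in cohort.trajectories:
        if len(traj) < 2:
            continue
        counts = np.zeros((3, 3))
        for a, b in markov_pairs(traj, low, high):
            counts[a.value, b.value] += 1
        row_sums = counts.sum(axis=1)
        for r in range(3):
            if row_sums[r] > 0:
                acc[r] += counts[r] / row_sums[r]
                n_per_row[r] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = acc / n_per_row[:, None]
    probs[n_per_row == 0] = np.nan
    return probs, n_per_row


@dataclass(frozen=True)
class ZoneDistribution:
    """Counts and percentages of all measurements per zone."""

    counts: dict[Zone, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[Zone, float]:
        total = self.n_total
        return {z: 100.0 * n / total for z, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone": [z.label for z in ZONES],
                "count": [self.counts[z] for z in ZONES],
                "percent": [self.percentages[z] for z in ZONES],
            }
        )


def zone_distribution(
    cohort: Cohort, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> ZoneDistribution:
    """Zone distribution over ALL measurements of a cohort."""
    if cohort.n_patients == 0:
        raise EmptyCohortError(f"cohort {cohort.label!r} has no trajectories")
    counts = {z: 0 for z in ZONES}
    for traj in cohort.trajectories:
        for c in traj.concentrations:
            counts[classify_zone(c, low, high)] += 1
    return ZoneDistribution(counts)
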