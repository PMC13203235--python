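"""Data model, file I/O, ordering and inclusion filtering for trough cohorts.

The canonical on-disk representation is a tidy delimited table with columns
``patient_id, cohort, seq_index, trough_mg_per_l[, timestamp]``.  Measurement
order within a patient is defined by ``seq_index``; timestamps are optional
metadata and never used for ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    IntegrityError,
    RowValidationError,
    SchemaError,
    ConfigurationError,
)

REQUIRED_COLUMNS = ("patient_id", "cohort", "seq_index", "trough_mg_per_l")
OPTIONAL_COLUMNS = ("timestamp",)

COVARIATE_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "egfr",
    "weight_kg",
    "therapy_days",
    "n_dose_adjustments",
    "loading_dose_mg_per_kg",
    "loading_dose_given",
)


@dataclass(frozen=True)
class TroughMeasurement:
    """One documented trough concentration for one patient."""

    patient_id: str
    cohort: str
    seq_index: int
    concentration: float
    timestamp: str | None = None


@dataclass(frozen=True)
class TroughTrajectory:
    """A patient's ordered sequence of trough concentrations (mg/L)."""

    patient_id: str
    cohort: str
    concentrations: tuple[float, ...]

    def __post_init__(self):
        if len(self.concentrations) < 1:
            raise RowValidationError(
                f"trajectory for {self.patient_id} is empty"
            )
        if any(c <= 0 or not math.isfinite(c) for c in self.concentrations):
            raise RowValidationError(
                f"trajectory for {self.patient_id} contains a non-positive "
                "or non-finite concentration"
            )

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class PatientCovariates:
    """Per-patient clinical covariates used in the exploratory layer."""

    patient_id: str
    age: float | None = None
    sex: str | None = None
    egfr: float | None = None
    weight: float | None = None
    therapy_duration: float | None = None
    n_dose_adjustments: float | None = None
    loading_dose: float | None = None
    loading_dose_given: bool | None = None


@dataclass(frozen=True)
class Cohort:
    """A labelled collection of trough trajectories with unique patients."""

    label: str
    trajectories: tuple[TroughTrajectory, ...]

    def __post_init__(self):
        ids = [t.patient_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"duplicate patient_id in cohort {self.label!r}")
        for t in self.trajectories:
            if t.cohort != self.label:
                raise IntegrityError(
                    f"trajectory {t.patient_id!r} has cohort {t.cohort!r}, "
                    f"expected {self.label!r}"
                )

    @property
    def n_patients(self) -> int:
        return len(self.trajectories)

    @property
    def n_measurements(self) -> int:
        return sum(len(t) for t in self.trajectories)

    def lengths(self) -> list[int]:
        return [len(t) for t in self.trajectories]


def _parse_concentration(raw, row: int, decimal: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise RowValidationError("missing concentration", row=row)
    text = str(raw).strip()
    if decimal != ".":
        text = text.replace(decimal, ".")
    # tolerate the unicode minus that copy-pasted clinical exports contain
    text = text.replace("−", "-")
    try:
        value = float(text)
    except ValueError:
        raise RowValidationError(
            f"non-numeric concentration {raw!r}", row=row
        ) from None
    if not math.isfinite(value) or value <= 0:
        raise RowValidationError(
            f"non-positive concentration {value!r}", row=row
        )
    return value


def _parse_seq_index(raw, row: int) -> int:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise RowValidationError("missing seq_index", row=row)
    try:
        value = int(str(raw).strip())
    except ValueError:
        raise RowValidationError(f"non-integer seq_index {raw!r}", row=row) from None
    if value < 1:
        raise RowValidationError(f"seq_index must be >= 1, got {value}", row=row)
    return value


def read_trough_table(
    path: str | Path,
    *,
    sep: str | None = None,
    decimal: str = ".",
) -> dict[str, Cohort]:
    """Read a delimited trough table into one :class:`Cohort` per label.

    Parameters
    ----------
    path:
        Delimited text file with a header row.  Required columns:
        ``patient_id, cohort, seq_index, trough_mg_per_l``.
    sep:
        Field separator; ``None`` autodetects CSV/TSV.
    decimal:
        Decimal mark used in the concentration column.

    Returns
    -------
    dict mapping cohort label to :class:`Cohort`, in order of first
    appearance.  At most two distinct labels are allowed — the comparison
    layer is strictly two-sample.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_ts = "timestamp" in df.columns

    measurements: list[TroughMeasurement] = []
    seen_keys: set[tuple[str, int]] = set()
    patient_cohort: dict[str, str] = {}
    for pos, rec in enumerate(df.itertuples(index=False)):
        row = pos + 2  # header is line 1
        pid = str(getattr(rec, "patient_id")).strip()
        cohort = str(getattr(rec, "cohort")).strip()
        if not pid or pid == "nan":
            raise RowValidationError("missing patient_id", row=row)
        if not cohort or cohort == "nan":
            raise RowValidationError("missing cohort label", row=row)
        seq = _parse_seq_index(getattr(rec, "seq_index"), row)
        conc = _parse_concentration(getattr(rec, "trough_mg_per_l"), row, decimal)
        key = (pid, seq)
        if key in seen_keys:
            raise IntegrityError(
                f"duplicate (patient_id, seq_index) = ({pid!r}, {seq})"
            )
        seen_keys.add(key)
        if pid in patient_cohort and patient_cohort[pid] != cohort:
            raise IntegrityError(
                f"patient {pid!r} appears in cohorts "
                f"{patient_cohort[pid]!r} and {cohort!r}"
            )
        patient_cohort[pid] = cohort
        ts = getattr(rec, "timestamp") if has_ts else None
        if isinstance(ts, float) and math.isnan(ts):
            ts = None
        measurements.append(TroughMeasurement(pid, cohort, seq, conc, ts))

    labels = list(dict.fromkeys(m.cohort for m in measurements))
    if len(labels) > 2:
        raise SchemaError(
            f"expected at most two cohort labels, found {len(labels)}: {labels}"
        )

    return build_cohorts(measurements)


def build_cohorts(measurements: Iterable[TroughMeasurement]) -> dict[str, Cohort]:
    """Group validated measurements by cohort and patient, ordered by seq_index."""
    by_patient: dict[str, list[TroughMeasurement]] = {}
    order: list[str] = []
    for m in measurements:
        if m.patient_id not in by_patient:
            by_patient[m.patient_id] = []
            order.append(m.patient_id)
        by_patient[m.patient_id].append(m)

    cohorts: dict[str, list[TroughTrajectory]] = {}
    for pid in order:
        rows = sorted(by_patient[pid], key=lambda m: m.seq_index)
        traj = TroughTrajectory(
            patient_id=pid,
            cohort=rows[0].cohort,
            concentrations=tuple(m.concentration for m in rows),
        )
        cohorts.setdefault(traj.cohort, []).append(traj)
    return {label: Cohort(label, tuple(ts)) for label, ts in cohorts.items()}


def write_trough_table(cohorts: Mapping[str, Cohort] | Cohort, path: str | Path) -> None:
    """Write cohorts back to the canonical tidy CSV schema."""
    if isinstance(cohorts, Cohort):
        cohorts = {cohorts.label: cohorts}
    records = []
    for cohort in cohorts.values():
        for traj in cohort.trajectories:
            for i, c in enumerate(traj.concentrations, start=1):
                records.append(
                    {
                        "patient_id": traj.patient_id,
                        "cohort": traj.cohort,
                        "seq_index": i,
                        "trough_mg_per_l": repr(c),
                    }
                )
    pd.DataFrame.from_records(
        records, columns=list(REQUIRED_COLUMNS)
    ).to_csv(path, index=False)


def filter_min_measurements(cohort: Cohort, k: int) -> Cohort:
    """Return a new cohort retaining only trajectories with >= ``k`` values.

    The input cohort is never modified; an empty result is allowed.
    """
    if k < 1:
        raise ConfigurationError(f"minimum measurement count must be >= 1, got {k}")
    kept = tuple(t for t in cohort.trajectories if len(t) >= k)
    return Cohort(cohort.label, kept)


def _opt_float(raw, row: int, name: str) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text in ("", "nan", "NA", "None"):
        return None
    try:
        value = float(text)
    except ValueError:
        raise RowValidationError(f"non-numeric {name} {raw!r}", row=row) from None
    if value < 0:
        raise RowValidationError(f"negative {name} {value!r}", row=row)
    return value


def _opt_bool(raw, row: int, name: str) -> bool | None:
    if raw is None:
        return None
    text = str(raw).strip().lower()
    if text in ("", "nan", "na", "none"):
        return None
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n"):
        return False
    raise RowValidationError(f"non-boolean {name} {raw!r}", row=row)


def read_covariates_table(
    path: str | Path, *, sep: str | None = None
) -> dict[str, PatientCovariates]:
    """Read the per-patient covariate table keyed by patient_id."""
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if "patient_id" not in df.columns:
        raise SchemaError("missing required column(s): patient_id")
    out: dict[str, PatientCovariates] = {}
    for pos, rec in enumerate(df.itertuples(index=False)):
        row = pos + 2
        pid = str(getattr(rec, "patient_id")).strip()
        if not pid or pid == "nan":
            raise RowValidationError("missing patient_id", row=row)
        if pid in out:
            raise IntegrityError(f"duplicate patient_id {pid!r} in covariates")
        get = lambda col: getattr(rec, col, None) if col in df.columns else None
        sex = get("sex")
        if isinstance(sex, float) and math.isnan(sex):
            sex = None
        out[pid] = PatientCovariates(
            patient_id=pid,
            age=_opt_float(get("age"), row, "age"),
            sex=str(sex).strip() if sex is not None else None,
            egfr=_opt_float(get("egfr"), row, "egfr"),
            weight=_opt_float(get("weight_kg"), row, "weight_kg"),
            therapy_duration=_opt_float(get("therapy_days"), row, "therapy_days"),
            n_dose_adjustments=_opt_float(
                get("n_dose_adjustments"), row, "n_dose_adjustments"
            ),
            loading_dose=_opt_float(
                get("loading_dose_mg_per_kg"), row, "loading_dose_mg_per_kg"
            ),
            loading_dose_given=_opt_bool(
                get("loading_dose_given"), row, "loading_dose_given"
            ),
        )
    return out


def write_covariates_table(
    covariates: Mapping[str, PatientCovariates], path: str | Path
) -> None:
    records = []
    for cov in covariates.values():
        records.append(
            {
                "patient_id": cov.patient_id,
                "age": cov.age,
                "sex": cov.sex,
                "egfr": cov.egfr,
                "weight_kg": cov.weight,
                "therapy_days": cov.therapy_duration,
                "n_dose_adjustments": cov.n_dose_adjustments,
                "loading_dose_mg_per_kg": cov.loading_dose,
                "loading_dose_given": (
                    None
                    if cov.loading_dose_given is None
                    else int(cov.loading_dose_given)
                ),
            }
        )
    pd.DataFrame.from_records(records, columns=list(COVARIATE_COLUMNS)).to_csv(
        path, index=False
    )
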