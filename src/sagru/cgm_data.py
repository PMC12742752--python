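"""CGM data model, CSV I/O, and validation / exclusion logic.

A continuous glucose monitor (CGM) worn by a hospitalized patient samples
interstitial glucose nominally every 15 minutes (96 readings per day).
This module defines the in-memory containers (:class:`GlucoseReading`,
:class:`PatientSeries`, :class:`Cohort`), a plain CSV dialect for them, and
the study-style inclusion rules: a patient is excluded when the trace has a
recording interruption longer than one day, or contains a zero or
out-of-range glucose value; otherwise the trace is split into contiguous
segments at every non-nominal sampling gap, so that downstream windowing
never spans a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Conversion factor between mmol/L and mg/dL glucose. 18.0 is the only
#: factor consistent with the standard clinical threshold pairs
#: (3.0 mmol/L = 54 mg/dL, 10.0 mmol/L = 180 mg/dL).
MGDL_PER_MMOL = 18.0

#: Default plausibility bounds for a glucose reading, mg/dL. Readings
#: outside this interval are treated as sensor artifacts and exclude the
#: patient. The interval doubles as the min-max normalization range.
DEFAULT_OUTLIER_BOUNDS = (39.6, 500.4)

CSV_COLUMNS = ("patient_id", "timestamp", "glucose")


class CGMFormatError(ValueError):
    """The input file does not conform to the CGM CSV dialect."""


class CGMValidationError(ValueError):
    """The input parses but violates a data invariant (e.g. duplicates)."""


def convert_units(value):
    """Convert glucose from mmol/L to mg/dL (multiply by 18.0).

    Parameters
    ----------
    value : float or array-like
        Glucose concentration in mmol/L; must be non-negative.

    Returns
    -------
    float or ndarray
        The same quantity in mg/dL.

    Examples
    --------
    >>> convert_units(3.0)
    54.0
    >>> convert_units(10.0)
    180.0
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glucose concentration cannot be negative")
    out = arr * MGDL_PER_MMOL
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass(frozen=True)
class GlucoseReading:
    """One timestamped CGM glucose reading in mg/dL."""

    timestamp: datetime
    glucose: float

    def __post_init__(self):
        if not self.glucose > 0:
            raise CGMValidationError(
                f"glucose must be positive, got {self.glucose!r} at {self.timestamp}"
            )


@dataclass
class PatientSeries:
    """One patient's ordered CGM trace at a nominal 15-minute cadence."""

    patient_id: str
    readings: list[GlucoseReading]
    cadence_minutes: int = 15

    def __post_init__(self):
        ts = [r.timestamp for r in self.readings]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise CGMValidationError(
                f"timestamps for patient {self.patient_id!r} must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def timestamps(self) -> list[datetime]:
        return [r.timestamp for r in self.readings]

    @property
    def glucose_values(self) -> np.ndarray:
        """Glucose values in mg/dL as a float array."""
        return np.array([r.glucose for r in self.readings], dtype=float)


@dataclass
class Cohort:
    """A named collection of patient series with unique patient ids."""

    patients: list[PatientSeries]
    name: str = ""

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CGMValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def subset(self, ids: Iterable[str], name: str = "") -> "Cohort":
        wanted = set(ids)
        return Cohort([p for p in self.patients if p.patient_id in wanted], name=name)

    def total_readings(self) -> int:
        return sum(len(p) for p in self.patients)


def read_cgm_csv(path, unit: str = "mg/dL") -> Cohort:
    """Read a cohort from the package CSV dialect.

    The file must have columns ``patient_id,timestamp,glucose`` (an optional
    ``unit`` column overrides the ``unit`` argument per row). Timestamps are
    ISO 8601. Glucose given in mmol/L is converted to mg/dL on ingestion so
    that the in-memory representation is always mg/dL.

    Raises
    ------
    CGMFormatError
        Missing columns, or an unparseable timestamp (reported with its
        1-based data row number).
    CGMValidationError
        Duplicate (patient_id, timestamp) pairs or non-positive glucose.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CGMFormatError(f"missing required column(s) {missing} in {path}")
    if df.empty:
        return Cohort([], name=path.stem)

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(ts.isna().idxmax()) + 1  # 1-based data row
        raise CGMFormatError(
            f"unparseable timestamp {df['timestamp'].iloc[row - 1]!r} at data row {row}"
        )
    df = df.assign(timestamp=ts)

    dup = df.duplicated(subset=["patient_id", "timestamp"])
    if dup.any():
        pid = df.loc[dup, "patient_id"].iloc[0]
        when = df.loc[dup, "timestamp"].iloc[0]
        raise CGMValidationError(f"duplicate reading for patient {pid!r} at {when}")

    if "unit" in df.columns:
        units = df["unit"].astype(str)
    else:
        units = pd.Series([unit] * len(df))
    glucose = df["glucose"].astype(float).to_numpy().copy()
    mmol = units.str.strip().str.lower().isin(("mmol/l", "mmol")).to_numpy()
    glucose[mmol] = glucose[mmol] * MGDL_PER_MMOL

    df = df.assign(glucose_mgdl=glucose)
    patients = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("timestamp")
        readings = [
            GlucoseReading(t.to_pydatetime(), g)
            for t, g in zip(grp["timestamp"], grp["glucose_mgdl"])
        ]
        patients.append(PatientSeries(str(pid), readings))
    return Cohort(patients, name=path.stem)


def write_cgm_csv(cohort: Cohort, path) -> None:
    """Write a cohort in the package CSV dialect (always mg/dL)."""
    rows = [
        {
            "patient_id": p.patient_id,
            "timestamp": r.timestamp.isoformat(timespec="minutes"),
            "glucose": repr(r.glucose),
            "unit": "mg/dL",
        }
        for p in cohort
        for r in p.readings
    ]
    pd.DataFrame(rows, columns=["patient_id", "timestamp", "glucose", "unit"]).to_csv(
        path, index=False
    )


@dataclass
class ValidationResult:
    """Outcome of series validation.

    ``verdict`` is ``"included"`` or ``"excluded"``; ``reasons`` lists the
    exclusion causes; ``segments`` (included series only) holds the maximal
    runs of consecutive readings exactly one nominal cadence apart, as
    ``(start, stop)`` half-open index pairs into the series.
    """

    verdict: str
    reasons: list[str] = field(default_factory=list)
    segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def included(self) -> bool:
        return self.verdict == "included"


def validate_series(
    series: PatientSeries,
    max_gap: timedelta = timedelta(days=1),
    outlier_bounds: tuple[float, float] = DEFAULT_OUTLIER_BOUNDS,
    cadence_tol_seconds: float = 90.0,
) -> ValidationResult:
    """Apply the exclusion rules and segment an included series.

    A series is *excluded* when any inter-reading gap exceeds ``max_gap``
    (default 1 day) or any glucose value is 0 / outside ``outlier_bounds``.
    Otherwise it is *included* and split into maximal contiguous segments:
    a segment boundary is placed wherever consecutive timestamps are not
    ``cadence_minutes`` apart within ``cadence_tol_seconds`` (sensor clocks
    jitter; 90 s tolerance by default).
    """
    if len(series) == 0:
        raise ValueError("cannot validate an empty series")

    reasons = []
    g = series.glucose_values
    lo, hi = outlier_bounds
    bad = (g <= 0) | (g < lo) | (g > hi)
    if bad.any():
        i = int(np.argmax(bad))
        reasons.append(
            f"abnormal glucose reading {g[i]:g} mg/dL at index {i} "
            f"(allowed [{lo:g}, {hi:g}])"
        )

    ts = series.timestamps
    gaps = [b - a for a, b in zip(ts, ts[1:])]
    too_long = [i for i, d in enumerate(gaps) if d > max_gap]
    if too_long:
        i = too_long[0]
        reasons.append(f"recording interruption of {gaps[i]} after index {i} exceeds {max_gap}")

    if reasons:
        return ValidationResult("excluded", reasons=reasons)

    nominal = timedelta(minutes=series.cadence_minutes)
    tol = timedelta(seconds=cadence_tol_seconds)
    segments = []
    start = 0
    for i, d in enumerate(gaps):
        if abs(d - nominal) > tol:
            segments.append((start, i + 1))
            start = i + 1
    segments.append((start, len(series)))
    return ValidationResult("included", segments=segments)


def validate_cohort(
    cohort: Cohort, **kwargs
) -> tuple[Cohort, dict[str, ValidationResult]]:
    """Validate every patient; return the included sub-cohort and a report."""
    report = {p.patient_id: validate_series(p, **kwargs) for p in cohort}
    kept = [p for p in cohort if report[p.patient_id].included]
    return Cohort(kept, name=cohort.name), report
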