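"""Feature encoding, normalization, and sliding-window dataset construction.

Each model input window is 8 consecutive readings (2 hours at the 15-min
cadence), with two features per step: the clock time encoded as decimal
hours (optionally rescaled to [0, 1] by dividing by 24) and the glucose
value min-max normalized to [0, 1] over a fixed clinical range. The
supervised target is the raw glucose (mg/dL) ``horizon_steps`` readings
past the window's last step: 2 steps for a 30-minute forecast, 4 for
60 minutes. Windows never span a segment boundary, so no input or target
ever bridges a recording gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

from sagru.cgm_data import Cohort, validate_cohort

DEFAULT_WINDOW_LEN = 8


@dataclass(frozen=True)
class NormalizationBounds:
    """Fixed min-max range for glucose normalization, mg/dL.

    The defaults span well beyond the clinical thresholds, so every
    plausible reading maps inside [0, 1].
    """

    x_min: float = 39.6
    x_max: float = 500.4

    def __post_init__(self):
        if not self.x_max > self.x_min:
            raise ValueError(f"x_max must exceed x_min, got [{self.x_min}, {self.x_max}]")


def encode_time(hour, minute=None):
    """Encode a clock time hh:mm as decimal hours (11:30 -> 11.5).

    Accepts either ``encode_time(hh, mm)``, an ``"hh:mm"`` string, or a
    ``datetime``/``time`` object.
    """
    if minute is None:
        if isinstance(hour, str):
            hh, mm = hour.split(":")
            hour, minute = int(hh), int(mm)
        elif isinstance(hour, datetime) or hasattr(hour, "hour"):
            hour, minute = hour.hour, hour.minute + getattr(hour, "second", 0) / 60.0
        else:
            raise TypeError(f"cannot encode {hour!r} as a clock time")
    if not (0 <= hour < 24):
        raise ValueError(f"hour out of range: {hour}")
    if not (0 <= minute < 60):
        raise ValueError(f"minute out of range: {minute}")
    return hour + minute / 60.0


def normalize_glucose(x, bounds: NormalizationBounds = NormalizationBounds()):
    """Min-max normalize glucose: (x - x_min) / (x_max - x_min).

    In-bounds glucose maps to [0, 1]; out-of-bounds input is passed through
    the same affine map (the caller decides what to do with it).
    """
    x = np.asarray(x, dtype=float)
    out = (x - bounds.x_min) / (bounds.x_max - bounds.x_min)
    return float(out) if out.ndim == 0 else out


def denormalize_glucose(x, bounds: NormalizationBounds = NormalizationBounds()):
    """Exact inverse of :func:`normalize_glucose`."""
    x = np.asarray(x, dtype=float)
    out = x * (bounds.x_max - bounds.x_min) + bounds.x_min
    return float(out) if out.ndim == 0 else out


@dataclass
class EncodedSegment:
    """One contiguous run of readings with encoded features.

    ``times_hours`` keeps the unscaled decimal hour (for reporting and
    attention analysis); ``glucose_mgdl`` keeps the raw value. The model
    input features are derived from these at window-build time.
    """

    patient_id: str
    segment_index: int
    times_hours: np.ndarray
    glucose_mgdl: np.ndarray

    def __len__(self) -> int:
        return len(self.glucose_mgdl)


def encode_cohort(cohort: Cohort, **validate_kwargs) -> list[EncodedSegment]:
    """Validate a cohort and encode the segments of every included patient."""
    included, report = validate_cohort(cohort, **validate_kwargs)
    segments = []
    for patient in included:
        times = np.array([encode_time(t) for t in patient.timestamps])
        glucose = patient.glucose_values
        for k, (a, b) in enumerate(report[patient.patient_id].segments):
            segments.append(EncodedSegment(patient.patient_id, k, times[a:b], glucose[a:b]))
    return segments


@dataclass
class WindowDataset:
    """Supervised windows for one forecasting horizon.

    Attributes
    ----------
    inputs : ndarray, shape (W, L, 2)
        Model features per window: column 0 the time feature (decimal hours
        / 24 when ``time_scaled``), column 1 normalized glucose.
    targets : ndarray, shape (W,)
        Glucose in mg/dL, ``horizon_steps`` readings past each window's end.
    window_times / window_glucose : ndarray, shape (W, L)
        Unscaled decimal hours and raw mg/dL for each input step — used for
        the persistence baseline and attention reporting.
    patient_ids, segment_idx, start_idx
        Per-window provenance.
    """

    inputs: np.ndarray
    targets: np.ndarray
    horizon_steps: int
    window_times: np.ndarray
    window_glucose: np.ndarray
    patient_ids: np.ndarray
    segment_idx: np.ndarray
    start_idx: np.ndarray
    bounds: NormalizationBounds = field(default_factory=NormalizationBounds)
    time_scaled: bool = True

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def last_observed_mgdl(self) -> np.ndarray:
        """Last input-step glucose per window (the persistence forecast)."""
        return self.window_glucose[:, -1]

    def save(self, path) -> None:
        """Serialize to an ``.npz`` container (arrays + scalar metadata)."""
        np.savez(
            path,
            inputs=self.inputs,
            targets=self.targets,
            horizon_steps=self.horizon_steps,
            window_times=self.window_times,
            window_glucose=self.window_glucose,
            patient_ids=self.patient_ids.astype(str),
            segment_idx=self.segment_idx,
            start_idx=self.start_idx,
            bounds=np.array([self.bounds.x_min, self.bounds.x_max]),
            time_scaled=self.time_scaled,
        )

    @classmethod
    def load(cls, path) -> "WindowDataset":
        z = np.load(path, allow_pickle=False)
        return cls(
            inputs=z["inputs"],
            targets=z["targets"],
            horizon_steps=int(z["horizon_steps"]),
            window_times=z["window_times"],
            window_glucose=z["window_glucose"],
            patient_ids=z["patient_ids"],
            segment_idx=z["segment_idx"],
            start_idx=z["start_idx"],
            bounds=NormalizationBounds(*z["bounds"]),
            time_scaled=bool(z["time_scaled"]),
        )

    def subset(self, mask_or_idx) -> "WindowDataset":
        i = np.asarray(mask_or_idx)
        return WindowDataset(
            self.inputs[i], self.targets[i], self.horizon_steps,
            self.window_times[i], self.window_glucose[i],
            self.patient_ids[i], self.segment_idx[i], self.start_idx[i],
            self.bounds, self.time_scaled,
        )


def window_count(n_readings: int, horizon_steps: int, window_len: int = DEFAULT_WINDOW_LEN,
                 stride: int = 1) -> int:
    """Number of stride-1 windows a segment of N readings yields:
    max(0, N - window_len - horizon_steps + 1), thinned by the stride."""
    full = n_readings - window_len - horizon_steps + 1
    if full <= 0:
        return 0
    return (full + stride - 1) // stride


def build_windows(
    segments: Sequence[EncodedSegment],
    horizon_steps: int,
    window_len: int = DEFAULT_WINDOW_LEN,
    stride: int = 1,
    bounds: NormalizationBounds = NormalizationBounds(),
    time_scaled: bool = True,
) -> WindowDataset:
    """Slide windows over every contiguous segment.

    For each valid start index ``s`` the input is steps ``s .. s+L-1`` and
    the target is the raw mg/dL glucose at index ``s + L - 1 + horizon_steps``
    of the same segment, i.e. exactly ``horizon_steps x 15`` minutes after
    the last observed input.
    """
    if horizon_steps < 1:
        raise ValueError("horizon_steps must be >= 1")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    inputs, targets, wt, wg, pids, segs, starts = [], [], [], [], [], [], []
    for seg in segments:
        n = len(seg)
        last_start = n - window_len - horizon_steps
        for s in range(0, last_start + 1, stride):
            t = seg.times_hours[s : s + window_len]
            g = seg.glucose_mgdl[s : s + window_len]
            feat_t = t / 24.0 if time_scaled else t
            feat_g = normalize_glucose(g, bounds)
            inputs.append(np.stack([feat_t, feat_g], axis=1))
            targets.append(seg.glucose_mgdl[s + window_len - 1 + horizon_steps])
            wt.append(t)
            wg.append(g)
            pids.append(seg.patient_id)
            segs.append(seg.segment_index)
            starts.append(s)

    L = window_len
    return WindowDataset(
        inputs=np.array(inputs, dtype=float).reshape(len(targets), L, 2),
        targets=np.array(targets, dtype=float),
        horizon_steps=horizon_steps,
        window_times=np.array(wt, dtype=float).reshape(len(targets), L),
        window_glucose=np.array(wg, dtype=float).reshape(len(targets), L),
        patient_ids=np.array(pids, dtype=object),
        segment_idx=np.array(segs, dtype=int),
        start_idx=np.array(starts, dtype=int),
        bounds=bounds,
        time_scaled=time_scaled,
    )


def windows_from_cohort(
    cohort: Cohort,
    horizon_minutes: int,
    cadence_minutes: int = 15,
    **build_kwargs,
) -> WindowDataset:
    """Validate, encode, and window a cohort for a horizon given in minutes."""
    if horizon_minutes % cadence_minutes != 0:
        raise ValueError(
            f"horizon {horizon_minutes} min is not a multiple of the {cadence_minutes}-min cadence"
        )
    steps = horizon_minutes // cadence_minutes
    return build_windows(encode_cohort(cohort), steps, **build_kwargs)
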