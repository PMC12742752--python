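"""Evaluation metrics for glucose forecasts.

Point accuracy: RMSE and MAE in mg/dL, and MARD (mean absolute relative
difference, in percent) — the standard CGM accuracy triple::

    RMSE = sqrt(mean((Y' - Y)^2))
    MAE  = mean(|Y' - Y|)
    MARD = mean(|Y' - Y| / Y) * 100

Clinical accuracy: the Clarke Error Grid partitions the (reference,
prediction) plane into zones A-E of increasing clinical risk; zone
boundaries follow the canonical 1987 grid. Event detection: accuracy /
precision / recall on binary adverse-event labels. Repeated-run
comparison: two-sided paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from sagru.events import GlucoseThresholds, DEFAULT_THRESHOLDS, label_predictions

logger = logging.getLogger(__name__)

CLARKE_ZONES = ("A", "B", "C", "D", "E")


def _pair(pred, ref):
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, ref


def rmse(pred, ref) -> float:
    """Root mean square error in mg/dL."""
    p, r = _pair(pred, ref)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def mae(pred, ref) -> float:
    """Mean absolute error in mg/dL."""
    p, r = _pair(pred, ref)
    return float(np.mean(np.abs(p - r)))


def mard(pred, ref) -> float:
    """Mean absolute relative difference, in percent of the reference."""
    p, r = _pair(pred, ref)
    if np.any(r <= 0):
        raise ValueError("MARD requires strictly positive reference glucose")
    return float(np.mean(np.abs(p - r) / r) * 100.0)


# ---------------------------------------------------------------------------
# Clarke Error Grid
# ---------------------------------------------------------------------------

def clarke_zones(pred, ref) -> np.ndarray:
    """Canonical Clarke Error Grid zone per (prediction, reference) pair.

    ``ref`` is the CGM/true glucose on the grid's x-axis, ``pred`` the
    forecast on the y-axis; both mg/dL, strictly positive. Returns an array
    of zone letters. Zone predicates (x = reference, y = prediction):

    - A: clinically accurate — y within 20% of x, or both in the
      hypoglycemic range (x <= 70 and y <= 70).
    - E: dangerous confusion of hypo and hyper — (x >= 180, y <= 70) or
      (x <= 70, y >= 180).
    - C: overcorrection — y >= x + 110 for 70 <= x <= 290, or
      y <= (7/5)x - 182 for 130 <= x <= 180.
    - D: failure to detect — normal-range prediction (70 <= y <= 180) while
      x >= 240 or x <= 175/3, or y >= (6/5)x for 175/3 <= x <= 70.
    - B: everything else (benign error).

    Evaluated in priority order A, E, C, D, B.
    """
    p, r = _pair(pred, ref)
    if np.any(p <= 0) or np.any(r <= 0):
        raise ValueError("Clarke grid requires positive glucose values")
    x, y = r, p

    # line comparisons are kept in integer-scaled form (5y <= 7x - 910
    # rather than y <= 1.4x - 182) so boundary points land exactly
    a = ((x <= 70) & (y <= 70)) | (5.0 * np.abs(y - x) <= x)
    e = ((x >= 180) & (y <= 70)) | ((x <= 70) & (y >= 180))
    c = ((x >= 70) & (x <= 290) & (y >= x + 110)) | (
        (x >= 130) & (x <= 180) & (5.0 * y <= 7.0 * x - 910.0)
    )
    d = ((x >= 240) & (y >= 70) & (y <= 180)) | (
        (3.0 * x <= 175.0) & (y >= 70) & (y <= 180)
    ) | ((3.0 * x >= 175.0) & (x <= 70) & (5.0 * y >= 6.0 * x))

    zones = np.select([a, e, c, d], ["A", "E", "C", "D"], default="B")
    return zones.astype(object)


def clarke_zone(pred: float, ref: float) -> str:
    """Zone letter for a single pair (see :func:`clarke_zones`)."""
    return str(clarke_zones([pred], [ref])[0])


def clarke_zone_counts(pred, ref) -> dict:
    """Zone letter -> pair count; counts always sum to the number of pairs."""
    z = clarke_zones(pred, ref)
    return {k: int(np.sum(z == k)) for k in CLARKE_ZONES}


# ---------------------------------------------------------------------------
# event-classification metrics
# ---------------------------------------------------------------------------

def classification_metrics(pred_labels, ref_labels):
    """Accuracy, precision, recall (percent) for binary adverse-event labels.

    Positive class = adverse. Precision (no predicted positives) or recall
    (no reference positives) with an undefined denominator is returned as
    ``None`` and logged, never coerced to 0.
    """
    p = np.asarray(pred_labels, dtype=bool).ravel()
    r = np.asarray(ref_labels, dtype=bool).ravel()
    if p.shape != r.shape:
        raise ValueError("label length mismatch")
    if p.size == 0:
        raise ValueError("no label pairs")
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    accuracy = 100.0 * (tp + tn) / p.size
    if tp + fp > 0:
        precision = 100.0 * tp / (tp + fp)
    else:
        precision = None
        logger.warning("precision undefined: no predicted positives")
    if tp + fn > 0:
        recall = 100.0 * tp / (tp + fn)
    else:
        recall = None
        logger.warning("recall undefined: no reference positives")
    return accuracy, precision, recall


# ---------------------------------------------------------------------------
# error distribution and repeated-run comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSummary:
    """Order statistics of the absolute prediction error, mg/dL.

    Quantiles use linear interpolation between order statistics; the
    standard deviation uses the n-1 denominator.
    """

    min: float
    q1: float
    median: float
    q3: float
    p95: float
    max: float
    sd: float


def abs_error_summary(pred, ref) -> ErrorSummary:
    """Summarize |pred - ref| with min / Q1 / median / Q3 / P95 / max / SD."""
    p, r = _pair(pred, ref)
    e = np.abs(p - r)
    q1, med, q3, p95 = np.quantile(e, [0.25, 0.5, 0.75, 0.95], method="linear")
    sd = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    return ErrorSummary(
        min=float(e.min()), q1=float(q1), median=float(med),
        q3=float(q3), p95=float(p95), max=float(e.max()), sd=sd,
    )


class DegenerateTTestError(ValueError):
    """Raised when the paired differences have zero variance."""


def paired_t_test(metric_a: Sequence[float], metric_b: Sequence[float]):
    """Two-sided paired t-test between per-repetition metric values.

    Returns ``(t, p)``. Requires at least two pairs and a nonzero variance
    of the differences (a constant difference makes t undefined).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D samples")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d, d[0], rtol=0.0, atol=0.0):
        raise DegenerateTTestError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def mean_sd(values) -> tuple[float, float]:
    """(mean, SD with n-1 denominator) over repetitions; SD = 0 for n = 1."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), (float(v.std(ddof=1)) if v.size > 1 else 0.0)


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """All evaluation outputs for one (model, horizon, repetition) run."""

    rmse: float
    mae: float
    mard: float
    clarke_counts: dict
    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    error_summary: ErrorSummary
    n: int

    def to_row(self, **extra) -> dict:
        row = {
            "rmse": self.rmse, "mae": self.mae, "mard": self.mard,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "n": self.n,
        }
        row.update({f"zone_{k}": v for k, v in self.clarke_counts.items()})
        row.update({f"abs_err_{k}": v for k, v in asdict(self.error_summary).items()})
        row.update(extra)
        return row


def evaluate_predictions(pred_mgdl, ref_mgdl,
                         thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS) -> MetricReport:
    """Compute the full metric suite for denormalized mg/dL predictions."""
    p, r = _pair(pred_mgdl, ref_mgdl)
    pred_ev, ref_ev = label_predictions(p, r, thresholds)
    accuracy, precision, recall = classification_metrics(pred_ev, ref_ev)
    return MetricReport(
        rmse=rmse(p, r),
        mae=mae(p, r),
        mard=mard(p, r),
        clarke_counts=clarke_zone_counts(p, r),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        error_summary=abs_error_summary(p, r),
        n=p.size,
    )
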