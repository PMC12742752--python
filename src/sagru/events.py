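"""Glycemic classification and adverse-event labeling.

Clinical thresholds (EASD): glucose below 70 mg/dL is hypoglycemic, at or
above 180 mg/dL hyperglycemic, anything between is normal. An *adverse
event* is any non-normal reading — hypo and hyper are pooled into one
binary positive class for event-detection metrics, with the three-way
label still available for per-class breakdowns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HYPOGLYCEMIA = "hypoglycemic"
NORMAL = "normal"
HYPERGLYCEMIA = "hyperglycemic"

#: Class order used for monotonicity: hypo < normal < hyper.
CLASS_ORDER = (HYPOGLYCEMIA, NORMAL, HYPERGLYCEMIA)


@dataclass(frozen=True)
class GlucoseThresholds:
    """Classification boundaries in mg/dL.

    ``hypo_below``: values strictly below are hypoglycemic (70 itself is
    normal). ``hyper_at_or_above``: values at or above are hyperglycemic
    (180 itself is hyperglycemic, the EASD convention ">=180"); set
    ``hyper_strict=True`` for a strictly-greater-than rule.
    """

    hypo_below: float = 70.0
    hyper_at_or_above: float = 180.0
    hyper_strict: bool = False

    def __post_init__(self):
        if not 0 < self.hypo_below < self.hyper_at_or_above:
            raise ValueError(
                f"need 0 < hypo ({self.hypo_below}) < hyper ({self.hyper_at_or_above})"
            )


DEFAULT_THRESHOLDS = GlucoseThresholds()


def classify_glucose(x, thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS):
    """Assign each positive mg/dL value to exactly one glycemic class.

    Scalars return a single label string; arrays return an object array of
    labels of the same shape.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("glucose must be positive")
    if thresholds.hyper_strict:
        hyper = arr > thresholds.hyper_at_or_above
    else:
        hyper = arr >= thresholds.hyper_at_or_above
    hypo = arr < thresholds.hypo_below
    labels = np.where(hypo, HYPOGLYCEMIA, np.where(hyper, HYPERGLYCEMIA, NORMAL))
    if arr.ndim == 0:
        return str(labels)
    return labels.astype(object)


def is_adverse(label):
    """True for any non-normal class label (works elementwise on arrays)."""
    arr = np.asarray(label)
    valid = np.isin(arr, CLASS_ORDER)
    if not valid.all():
        bad = arr[~valid].ravel()[0]
        raise ValueError(f"unknown glucose class label {bad!r}")
    out = arr != NORMAL
    if arr.ndim == 0:
        return bool(out)
    return out


def adverse_from_glucose(x, thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS):
    """Shortcut: is_adverse(classify_glucose(x))."""
    return is_adverse(classify_glucose(x, thresholds))


def label_predictions(predictions, references,
                      thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS):
    """Binary adverse-event labels for paired predicted/reference glucose.

    Returns ``(pred_labels, ref_labels)`` boolean arrays where True marks an
    adverse (hypo- or hyperglycemic) value. The prediction labels are what
    the model "raises" as events; the reference labels are the ground truth.
    """
    pred = np.asarray(predictions, dtype=float)
    ref = np.asarray(references, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"length mismatch: predictions {pred.shape} vs references {ref.shape}")
    return adverse_from_glucose(pred, thresholds), adverse_from_glucose(ref, thresholds)
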