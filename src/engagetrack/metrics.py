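"""Classifier-validation arithmetic and the motion-blur velocity model.

The trial classifier is validated against human expert scoring as a binary
classifier with "engaged" as the positive class.  This module holds the
confusion-matrix bookkeeping, the five percentage metrics (accuracy,
precision, sensitivity, specificity, F1), the Matthews correlation
coefficient, and the linear motion-blur velocity model that converts a
blur-kernel length into the animal speed it corresponds to under a given
camera geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

ENGAGED = "engaged"
DISTRACTED = "distracted"
_LABELS = frozenset({ENGAGED, DISTRACTED})


@dataclass(frozen=True)
class ConfusionMatrix:
    """Trial-level confusion counts; positive = engaged, negative = distracted."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one trial")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def truth_positive(self) -> int:
        """Trials the reference (human) scoring called engaged."""
        return self.TP + self.FN

    @property
    def predicted_positive(self) -> int:
        """Trials the tracking program called engaged."""
        return self.TP + self.FP


@dataclass(frozen=True)
class MetricsReport:
    """Percentage metrics plus MCC.  Undefined ratios are carried as None."""

    accuracy: float
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    mcc: float

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Display form: percents to one decimal, MCC to two."""
        out: dict[str, float | None] = {}
        for name in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        out["mcc"] = round(self.mcc, 2)
        return out


@dataclass(frozen=True)
class BlurVelocityParams:
    """Camera/optics parameters of the linear motion-blur model."""

    blur_kernel_size: float  # px
    frames_per_second: float  # Hz
    field_of_view_width: float  # cm
    resolution_width: float  # px

    def __post_init__(self) -> None:
        for name in ("blur_kernel_size", "frames_per_second",
                     "field_of_view_width", "resolution_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def confusion_from_labels(
    predicted: Sequence[str], truth: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix from paired label sequences.

    Labels must be "engaged" (positive) or "distracted" (negative);
    sequences must be equal-length and non-empty.
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predicted vs {len(truth)} truth")
    if len(predicted) == 0:
        raise ValueError("label sequences must be non-empty")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if p not in _LABELS or t not in _LABELS:
            raise ValueError(f"labels must be in {sorted(_LABELS)}")
        if t == ENGAGED:
            if p == ENGAGED:
                tp += 1
            else:
                fn += 1
        else:
            if p == ENGAGED:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


def confusion_from_marginals(
    total: int, truth_pos: int, pred_pos: int, FN: int
) -> ConfusionMatrix:
    """Reconstruct the unique confusion matrix from published marginals.

    A 2x2 matrix is fully determined by the trial total, the number of
    reference-positive trials, the number of predicted-positive trials and
    one cell (here FN).  Raises if the four linear constraints admit no
    non-negative solution.
    """
    tp = truth_pos - FN
    fp = pred_pos - tp
    tn = total - truth_pos - fp
    if min(tp, fp, tn, FN) < 0:
        raise ValueError("marginals admit no non-negative confusion matrix")
    if tn + FN != total - pred_pos:
        raise ValueError("marginals are mutually inconsistent")
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=FN)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity, F1 (percent) and MCC.

    Zero-denominator conventions: precision is None when no trial was
    predicted positive; sensitivity None when there are no reference
    positives; specificity None when no reference negatives; F1 None when
    either component is None or both are zero; MCC is 0 whenever any of
    its four marginal sums is zero (the standard limit convention).
    """
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    accuracy = (tp + tn) / cm.total * 100.0

    precision = tp / (tp + fp) * 100.0 if (tp + fp) > 0 else None
    sensitivity = tp / (tp + fn) * 100.0 if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) * 100.0 if (tn + fp) > 0 else None

    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        p, s = precision / 100.0, sensitivity / 100.0
        f1 = 2.0 * p * s / (p + s) * 100.0

    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq)

    return MetricsReport(accuracy=accuracy, precision=precision,
                         sensitivity=sensitivity, specificity=specificity,
                         f1=f1, mcc=mcc)


def blur_velocity(p: BlurVelocityParams) -> float:
    """Animal velocity (cm/s) corresponding to a linear blur kernel.

    A marker moving at velocity v smears over v / (fov_width/resolution *
    fps) pixels during one exposure; inverting gives
    v = kernel_px * fps * fov_width / resolution_width.
    """
    return (p.blur_kernel_size * p.frames_per_second
            * p.field_of_view_width / p.resolution_width)
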