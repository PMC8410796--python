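"""Operating-point evaluation: SEN/SPE, ROC/AUC, threshold sweeps and
model-versus-reader comparison.

Convention fixed throughout the package: an example is predicted positive
iff its score is **greater than or equal to** the threshold (ties go to the
positive class).  Threshold-sweep tables depend on this convention, so it is
stated here once and tested.

The ROC curve is computed over all distinct score thresholds (no
intermediate-point dropping) with sensitivity = TPR on the vertical axis and
1 - specificity = FPR on the horizontal axis; AUC is the trapezoidal area,
which equals the Mann-Whitney probability that a random positive outscores a
random negative (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidInputError, UndefinedMetricError
from .losses import ConfusionCounts

__all__ = [
    "ROCCurve",
    "OperatingPoint",
    "ReaderPoint",
    "sensitivity",
    "specificity",
    "accuracy",
    "confusion_at_threshold",
    "roc_and_auc",
    "threshold_sweep",
    "balanced_threshold",
    "readers_outperformed",
]


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN): recall on the positive (melanoma) class."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive examples")
    return counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP): recall on the negative (nevus) class."""
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative examples")
    return counts.tn / (counts.tn + counts.fp)


def accuracy(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty counts")
    return (counts.tp + counts.tn) / counts.total


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Hard counts with the score >= threshold positive-prediction rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-indexed (SEN, SPE) pairs, thresholds descending."""

    thresholds: np.ndarray
    sen: np.ndarray
    spe: np.ndarray
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.spe


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sen: float
    spe: float
    attained: bool = True  # False when a requested target was unattainable


@dataclass(frozen=True)
class ReaderPoint:
    """One human reader (or reader group) operating point."""

    sen: float
    spe: float
    group_label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.sen <= 1.0 and 0.0 <= self.spe <= 1.0):
            raise InvalidInputError("reader SEN/SPE must lie in [0, 1]")


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise UndefinedMetricError("ROC undefined: only one class present in labels")


def roc_and_auc(scores, labels) -> ROCCurve:
    """Full ROC over all distinct score thresholds, AUC by trapezoid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0 or scores.size != labels.size:
        raise InvalidInputError("scores and labels must have equal nonzero length")
    _check_two_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    sen = tpr
    spe = 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))
    # replace sklearn's +inf sentinel threshold by a value just above max score
    thr = thr.astype(float).copy()
    if np.isinf(thr[0]):
        thr[0] = scores.max() + 1.0
    return ROCCurve(thresholds=thr, sen=sen, spe=spe, auc=auc)


def _operating_points(scores, labels) -> list[OperatingPoint]:
    """All achievable operating points, one per candidate threshold.

    Candidates are the distinct scores (each the smallest threshold keeping
    a given prediction set) plus one threshold above all scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    candidates = np.unique(scores)[::-1]
    candidates = np.concatenate([[scores.max() + 1.0], candidates])
    points = []
    for t in candidates:
        c = confusion_at_threshold(scores, labels, t)
        points.append(OperatingPoint(threshold=float(t), sen=sensitivity(c), spe=specificity(c)))
    return points


def threshold_sweep(scores, labels, sen_targets=(), spe_targets=()) -> list[dict]:
    """Operating points meeting SEN (resp. SPE) floors.

    For each SEN target: the largest threshold achieving SEN >= target,
    reported with its SPE.  For each SPE target: the smallest threshold
    achieving SPE >= target, reported with its SEN (the mirror rule; SPE
    grows with the threshold).  Unattainable targets (possible only with
    degenerate score sets) are flagged and reported at the nearest boundary.
    Returns rows of {"target_kind", "target", "point": OperatingPoint}.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pts = _operating_points(scores, labels)
    rows: list[dict] = []
    for target in sen_targets:
        ok = [p for p in pts if p.sen >= target - 1e-12]
        if ok:
            best = max(ok, key=lambda p: p.threshold)
            point = OperatingPoint(best.threshold, best.sen, best.spe, attained=True)
        else:
            b = min(pts, key=lambda p: p.threshold)
            point = OperatingPoint(b.threshold, b.sen, b.spe, attained=False)
        rows.append({"target_kind": "sen", "target": float(target), "point": point})
    for target in spe_targets:
        ok = [p for p in pts if p.spe >= target - 1e-12]
        if ok:
            best = min(ok, key=lambda p: p.threshold)
            point = OperatingPoint(best.threshold, best.sen, best.spe, attained=True)
        else:
            b = max(pts, key=lambda p: p.threshold)
            point = OperatingPoint(b.threshold, b.sen, b.spe, attained=False)
        rows.append({"target_kind": "spe", "target": float(target), "point": point})
    return rows


def balanced_threshold(scores, labels, criterion: str = "min_gap") -> OperatingPoint:
    """Balanced operating point over all candidate thresholds.

    ``min_gap``: argmin |SEN - SPE| (ties broken by larger SEN + SPE, then
    larger threshold).  ``youden``: argmax SEN + SPE - 1 (ties by smaller
    |SEN - SPE|, then larger threshold).
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pts = _operating_points(scores, labels)
    if criterion == "min_gap":
        key = lambda p: (abs(p.sen - p.spe), -(p.sen + p.spe), -p.threshold)
    elif criterion == "youden":
        key = lambda p: (-(p.sen + p.spe - 1.0), abs(p.sen - p.spe), -p.threshold)
    else:
        raise InvalidInputError(f"unknown criterion {criterion!r}; use 'min_gap' or 'youden'")
    return min(pts, key=key)


def readers_outperformed(
    curve: ROCCurve, readers: list[ReaderPoint], tol: float = 1e-9
) -> tuple[int, list[str]]:
    """Count readers strictly below the model's interpolated ROC curve.

    A reader at (1-SPE, SEN) is *outperformed* when the curve, linearly
    interpolated at the reader's false-positive rate, lies strictly above
    the reader's sensitivity; readers on the curve (within ``tol``) are
    flagged ``"on-curve"``, those above as ``"above"``.
    Returns (count_outperformed, per-reader flags).
    """
    order = np.argsort(curve.fpr, kind="stable")
    fpr = curve.fpr[order]
    sen = curve.sen[order]
    flags = []
    n_out = 0
    for reader in readers:
        r_fpr = 1.0 - reader.spe
        model_sen = float(np.interp(r_fpr, fpr, sen))
        if reader.sen < model_sen - tol:
            flags.append("below")
            n_out += 1
        elif reader.sen <= model_sen + tol:
            flags.append("on-curve")
        else:
            flags.append("above")
    return n_out, flags
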