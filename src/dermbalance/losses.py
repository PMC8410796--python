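"""Class-wise loss family for imbalanced binary classification.

The central object is the custom balanced loss

    l_CLF = a * (l_PMSE + l_NMSE)**2 + b * (l_PMSE - l_NMSE)**2

where ``l_PMSE`` / ``l_NMSE`` are the mean squared errors restricted to the
positive (melanoma) and negative (nevus) examples of a mini-batch.  The sum
term drives both class-wise errors down; the difference term penalises an
imbalance between them, which on an imbalanced dataset is what pushes
sensitivity up to meet specificity.  Squaring both terms keeps the loss
non-negative and differentiable, so it can be minimised by backpropagation
on continuous sigmoid scores.

All losses come in two forms:

* functional, on a :class:`LabeledBatch` of continuous scores (used in
  training, with analytic gradients), and
* closed-form on hard :class:`ConfusionCounts` (used for verification and
  reporting), which agrees bit-for-bit with the functional form applied to
  0/1 scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "LabeledBatch",
    "LossParams",
    "ConfusionCounts",
    "ClasswiseLoss",
    "mse",
    "pmse",
    "nmse",
    "clf",
    "clf_gradient",
    "clf_from_confusion",
    "binary_cross_entropy",
    "focal_loss",
    "MSELoss",
    "BCELoss",
    "FocalLoss",
    "CLFLoss",
    "make_loss",
]

_EPS = 1e-7  # clipping for the log-based baselines only; CLF needs none


@dataclass(frozen=True)
class LabeledBatch:
    """Paired prediction scores in [0, 1] and binary ground-truth labels.

    ``labels`` uses 1 for the positive (melanoma) class and 0 for the
    negative (nevus) class.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or labels.ndim != 1:
            raise InvalidInputError("scores and labels must be 1-D vectors")
        if scores.size == 0 or scores.size != labels.size:
            raise InvalidInputError(
                f"scores and labels must have equal nonzero length, "
                f"got {scores.size} and {labels.size}"
            )
        if np.any(scores < 0.0) or np.any(scores > 1.0):
            raise InvalidInputError("scores must lie in [0, 1]")
        if not np.isin(labels, (0, 1)).all():
            raise InvalidInputError("labels must be exactly 0 or 1")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int64))

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())


@dataclass(frozen=True)
class LossParams:
    """Coefficients of the balanced loss: ``a`` weighs the squared sum of the
    class-wise errors, ``b`` the squared difference.  ``b > a`` makes the
    penalty harsher when sensitivity and specificity drift apart."""

    a: float = 0.5
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b <= 0:
            raise InvalidInputError(
                f"require a >= 0, b >= 0, a + b > 0; got a={self.a}, b={self.b}"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """Hard-label confusion matrix (positive = melanoma)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_batch(self) -> LabeledBatch:
        """Equivalent hard-scored batch (scores are 0/1 predictions)."""
        scores = np.concatenate(
            [
                np.ones(self.tp),
                np.zeros(self.fn),
                np.ones(self.fp),
                np.zeros(self.tn),
            ]
        )
        labels = np.concatenate(
            [np.ones(self.tp + self.fn, dtype=int), np.zeros(self.fp + self.tn, dtype=int)]
        )
        return LabeledBatch(scores=scores, labels=labels)


@dataclass(frozen=True)
class ClasswiseLoss:
    """The four losses of the family evaluated together."""

    mse: float
    pmse: float
    nmse: float
    clf: float


def _split(batch: LabeledBatch) -> tuple[np.ndarray, np.ndarray]:
    pos = batch.scores[batch.labels == 1]
    neg = batch.scores[batch.labels == 0]
    return pos, neg


def mse(batch: LabeledBatch) -> float:
    """Mean squared error over the whole batch."""
    return float(np.mean((batch.labels - batch.scores) ** 2))


def _one_class_mse(values: np.ndarray, target: float, name: str, strict: bool) -> float:
    if values.size == 0:
        if strict:
            raise InvalidInputError(f"{name} undefined: batch has no {name[0]}-class examples")
        warnings.warn(
            f"{name} requested on a batch with no matching examples; returning 0.0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return float(np.mean((target - values) ** 2))


def pmse(batch: LabeledBatch, *, strict: bool = True) -> float:
    """Mean squared error restricted to positive-labeled examples.

    With ``strict=False`` (training mode) a batch without positives yields
    0.0 with a warning instead of an error, so the loss stays total for
    unconstrained samplers.
    """
    pos, _ = _split(batch)
    return _one_class_mse(pos, 1.0, "pmse", strict)


def nmse(batch: LabeledBatch, *, strict: bool = True) -> float:
    """Mean squared error restricted to negative-labeled examples."""
    _, neg = _split(batch)
    return _one_class_mse(neg, 0.0, "nmse", strict)


def clf(batch: LabeledBatch, params: LossParams = LossParams(), *, strict: bool = True) -> float:
    """The balanced custom loss a*(pmse+nmse)^2 + b*(pmse-nmse)^2."""
    p = pmse(batch, strict=strict)
    n = nmse(batch, strict=strict)
    return params.a * (p + n) ** 2 + params.b * (p - n) ** 2


def clf_gradient(batch: LabeledBatch, params: LossParams = LossParams()) -> np.ndarray:
    """Analytic gradient of :func:`clf` with respect to the scores.

    With p = pmse, n = nmse:
      dl/dp = 2a(p+n) + 2b(p-n),  dl/dn = 2a(p+n) - 2b(p-n)
      dp/ds_i = -2(1-s_i)/P for positives, dn/ds_i = 2 s_i / N for negatives.
    Missing-class terms contribute a zero gradient.
    """
    scores, labels = batch.scores, batch.labels
    p = pmse(batch, strict=False) if batch.n_pos == 0 else pmse(batch)
    n = nmse(batch, strict=False) if batch.n_neg == 0 else nmse(batch)
    dl_dp = 2 * params.a * (p + n) + 2 * params.b * (p - n)
    dl_dn = 2 * params.a * (p + n) - 2 * params.b * (p - n)
    grad = np.zeros_like(scores)
    if batch.n_pos:
        mask = labels == 1
        grad[mask] = dl_dp * (-2.0 * (1.0 - scores[mask]) / batch.n_pos)
    if batch.n_neg:
        mask = labels == 0
        grad[mask] = dl_dn * (2.0 * scores[mask] / batch.n_neg)
    return grad


def clf_from_confusion(
    counts: ConfusionCounts, params: LossParams = LossParams()
) -> ClasswiseLoss:
    """Closed-form loss family on hard confusion counts.

    pmse = FN/(TP+FN), nmse = FP/(TN+FP), mse = (FN+FP)/M.  Agrees exactly
    with the functional forms applied to the equivalent 0/1-scored batch.
    """
    if counts.n_pos == 0 or counts.n_neg == 0:
        missing = "positive" if counts.n_pos == 0 else "negative"
        raise InvalidInputError(f"class-wise losses undefined: no {missing} examples")
    p = counts.fn / counts.n_pos
    n = counts.fp / counts.n_neg
    return ClasswiseLoss(
        mse=(counts.fn + counts.fp) / counts.total,
        pmse=p,
        nmse=n,
        clf=params.a * (p + n) ** 2 + params.b * (p - n) ** 2,
    )


def binary_cross_entropy(batch: LabeledBatch) -> float:
    """Standard BCE with scores clipped to [eps, 1-eps]; a baseline loss."""
    s = np.clip(batch.scores, _EPS, 1.0 - _EPS)
    y = batch.labels
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def focal_loss(batch: LabeledBatch, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Focal loss; reduces to alpha-weighted BCE at gamma = 0."""
    s = np.clip(batch.scores, _EPS, 1.0 - _EPS)
    y = batch.labels
    pt = np.where(y == 1, s, 1.0 - s)
    w = np.where(y == 1, alpha, 1.0 - alpha)
    return float(np.mean(-w * (1.0 - pt) ** gamma * np.log(pt)))


# --------------------------------------------------------------------------
# Trainable loss objects: value + gradient with respect to the scores.
# These are what the training loop consumes; the functional forms above are
# the reference semantics.


class _TrainableLoss:
    name: str = ""

    def value(self, scores: np.ndarray, labels: np.ndarray) -> float:
        raise NotImplementedError

    def grad(self, scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class MSELoss(_TrainableLoss):
    name = "mse"

    def value(self, scores, labels):
        return float(np.mean((labels - scores) ** 2))

    def grad(self, scores, labels):
        return 2.0 * (scores - labels) / scores.size


class BCELoss(_TrainableLoss):
    name = "bce"

    def value(self, scores, labels):
        return binary_cross_entropy(LabeledBatch(scores=scores, labels=labels))

    def grad(self, scores, labels):
        s = np.clip(scores, _EPS, 1.0 - _EPS)
        return (s - labels) / (s * (1.0 - s)) / scores.size


class FocalLoss(_TrainableLoss):
    name = "focal"

    def __init__(self, gamma: float = 2.0, alpha: float = 0.25):
        self.gamma = gamma
        self.alpha = alpha

    def value(self, scores, labels):
        return focal_loss(
            LabeledBatch(scores=scores, labels=labels), gamma=self.gamma, alpha=self.alpha
        )

    def grad(self, scores, labels):
        s = np.clip(scores, _EPS, 1.0 - _EPS)
        y = labels
        pt = np.where(y == 1, s, 1.0 - s)
        # d/dpt of -w (1-pt)^g log(pt), then dpt/ds = +1 for pos, -1 for neg
        w = np.where(y == 1, self.alpha, 1.0 - self.alpha)
        g = self.gamma
        dpt = -w * (-g * (1.0 - pt) ** (g - 1.0) * np.log(pt) + (1.0 - pt) ** g / pt)
        sign = np.where(y == 1, 1.0, -1.0)
        return dpt * sign / scores.size


class CLFLoss(_TrainableLoss):
    """Differentiable form of the balanced custom loss for training."""

    name = "clf"

    def __init__(self, params: LossParams = LossParams()):
        self.params = params

    def value(self, scores, labels):
        return clf(LabeledBatch(scores=scores, labels=labels), self.params, strict=False)

    def grad(self, scores, labels):
        return clf_gradient(LabeledBatch(scores=scores, labels=labels), self.params)


def make_loss(name: str, params: LossParams | None = None) -> _TrainableLoss:
    """Loss factory used by the training scenarios."""
    name = name.lower()
    if name == "mse":
        return MSELoss()
    if name == "bce":
        return BCELoss()
    if name == "focal":
        return FocalLoss()
    if name == "clf":
        return CLFLoss(params or LossParams())
    raise InvalidInputError(f"unknown loss {name!r}; expected mse, bce, focal or clf")
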