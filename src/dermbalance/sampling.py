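"""Mini-batch composition logic.

Two schedulers are provided:

* :func:`make_epoch` — the fixed-ratio sampler: every training batch carries
  exactly ``n_pos`` minority (positive) and ``batch_size - n_pos`` majority
  (negative) examples.  The per-batch class proportion is therefore a
  constant rather than a random variable, which is what makes a class-wise
  batch loss well conditioned on imbalanced data.
* :func:`naive_epoch` — the conventional uniform shuffle-and-chunk baseline,
  whose batches at low prevalence routinely contain zero positives.

An epoch of the fixed-ratio sampler is anchored to one full pass over the
majority class: negatives are a shuffled partition (each used exactly once),
while positives are drawn from an independently shuffled cycling stream that
reshuffles on exhaustion, so within each pass every positive is used exactly
once before any repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["SamplingPlan", "EpochSchedule", "make_epoch", "naive_epoch"]


@dataclass(frozen=True)
class SamplingPlan:
    """Fixed-ratio batch composition rule.

    ``positive_fraction`` is the target share of minority examples per batch
    (NPI / batch_size); by default callers set it to the training-set
    prevalence, and 0.5 gives fully balanced batches.
    """

    batch_size: int = 32
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise InvalidInputError("batch_size must be at least 2")
        if not (0.0 < self.positive_fraction < 1.0):
            raise InvalidInputError("positive_fraction must lie strictly in (0, 1)")
        n_pos = self.n_pos
        if not (1 <= n_pos <= self.batch_size - 1):
            raise InvalidInputError(
                f"positive_fraction {self.positive_fraction} with batch_size "
                f"{self.batch_size} gives n_pos={n_pos}, outside [1, batch_size-1]"
            )

    @property
    def n_pos(self) -> int:
        return int(round(self.positive_fraction * self.batch_size))

    @property
    def n_neg(self) -> int:
        return self.batch_size - self.n_pos


@dataclass
class EpochSchedule:
    """Realized batch index lists for one epoch."""

    batches: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.batches)

    def __iter__(self):
        return iter(self.batches)

    def dump(self, path) -> None:
        """Debug text dump: one line of comma-separated indices per batch."""
        with open(path, "w") as fh:
            for batch in self.batches:
                fh.write(",".join(map(str, batch.tolist())) + "\n")


def _as_label_vector(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise InvalidInputError("labels must be a non-empty 1-D vector")
    if not np.isin(labels, (0, 1)).all():
        raise InvalidInputError("labels must be 0/1")
    return labels.astype(np.int64)


def make_epoch(labels, plan: SamplingPlan, rng: np.random.Generator | None = None) -> EpochSchedule:
    """One epoch of fixed-ratio batches.

    Epoch length is ``floor(n_negatives / plan.n_neg)`` batches; a final
    short batch that could not honor the ratio is dropped.  Deterministic
    for a given ``plan.seed`` (or an explicitly passed generator).
    """
    labels = _as_label_vector(labels)
    rng = np.random.default_rng(plan.seed) if rng is None else rng
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if pos_idx.size < plan.n_pos:
        raise InvalidInputError(
            f"too few positive examples: need >= {plan.n_pos}, have {pos_idx.size}"
        )
    if neg_idx.size < plan.n_neg:
        raise InvalidInputError(
            f"too few negative examples: need >= {plan.n_neg}, have {neg_idx.size}"
        )
    n_batches = neg_idx.size // plan.n_neg
    neg_perm = rng.permutation(neg_idx)

    # positive cycling stream: concatenated independent shuffles
    need = n_batches * plan.n_pos
    chunks = []
    drawn = 0
    while drawn < need:
        chunks.append(rng.permutation(pos_idx))
        drawn += pos_idx.size
    pos_stream = np.concatenate(chunks)[:need]

    batches = []
    for b in range(n_batches):
        pos_part = pos_stream[b * plan.n_pos : (b + 1) * plan.n_pos]
        neg_part = neg_perm[b * plan.n_neg : (b + 1) * plan.n_neg]
        batch = np.concatenate([pos_part, neg_part])
        rng.shuffle(batch)  # avoid positional class structure within the batch
        batches.append(batch)
    return EpochSchedule(batches=batches)


def naive_epoch(labels, batch_size: int, rng: np.random.Generator | int | None = None) -> EpochSchedule:
    """Uniformly shuffled partition into batches; the ORI baseline.

    The last batch may be short; per-batch class counts are unconstrained.
    """
    labels = _as_label_vector(labels)
    if batch_size < 1:
        raise InvalidInputError("batch_size must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    elif rng is None:
        rng = np.random.default_rng(0)
    perm = rng.permutation(labels.size)
    batches = [perm[i : i + batch_size] for i in range(0, perm.size, batch_size)]
    return EpochSchedule(batches=batches)
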