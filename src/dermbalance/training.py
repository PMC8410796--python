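"""Scenario-driven training: ORI / BON / BLF with Adam, a triangular2
cyclical learning rate, and min-validation-loss checkpointing.

The three scenarios share one architecture and differ only in how batches
are composed and which loss is minimised:

* ``ORI`` — naive shuffled batches, a conventional loss (MSE by default);
* ``BON`` — fixed-ratio batches, conventional loss;
* ``BLF`` — fixed-ratio batches plus the balanced custom loss (CLF).

The learning rate follows the *triangular2* cyclical schedule: it ramps
linearly between ``base_lr`` and a ceiling over a half-cycle of
``step_size`` epochs, and the ceiling amplitude halves after every full
cycle.  Stepping is per iteration (per mini-batch).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, augment
from .errors import DivergenceError, InvalidInputError
from .losses import LossParams, make_loss
from .models import Classifier, HeadConfig, build_classifier
from .nn import Adam
from .sampling import SamplingPlan, make_epoch, naive_epoch
from .evaluation import confusion_at_threshold, sensitivity, specificity

__all__ = [
    "CLRConfig",
    "OptimizerConfig",
    "ScenarioConfig",
    "TrainingHistory",
    "clr_at",
    "train",
    "SCENARIOS",
]

SCENARIOS = ("ORI", "BON", "BLF")


@dataclass(frozen=True)
class CLRConfig:
    base_lr: float = 1e-7
    max_lr: float = 1e-4
    step_size_epochs: int = 4
    mode: str = "triangular2"

    def __post_init__(self) -> None:
        if not (0 < self.base_lr < self.max_lr):
            raise InvalidInputError("require 0 < base_lr < max_lr")
        if self.step_size_epochs < 1:
            raise InvalidInputError("step_size_epochs must be >= 1")
        if self.mode != "triangular2":
            raise InvalidInputError(f"unsupported CLR mode {self.mode!r}")


@dataclass(frozen=True)
class OptimizerConfig:
    kind: str = "adam"
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    decay: float = 0.0
    amsgrad: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("adam",):
            raise InvalidInputError("only the adam optimizer is implemented")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise InvalidInputError("betas must lie in (0, 1)")


@dataclass(frozen=True)
class ScenarioConfig:
    name: str = "BLF"
    loss: str = "clf"
    sampler: str = "fixed_ratio"
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    positive_fraction: float | None = None  # None -> training-set prevalence
    loss_params: LossParams = field(default_factory=LossParams)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise InvalidInputError(f"scenario must be one of {SCENARIOS}")
        valid = {
            "ORI": (("mse", "bce", "focal"), "naive"),
            "BON": (("mse", "bce", "focal"), "fixed_ratio"),
            "BLF": (("clf",), "fixed_ratio"),
        }
        losses, sampler = valid[self.name]
        if self.loss not in losses or self.sampler != sampler:
            raise InvalidInputError(
                f"scenario {self.name} requires loss in {losses} and sampler "
                f"{sampler!r}; got loss={self.loss!r}, sampler={self.sampler!r}"
            )
        if self.epochs < 1 or self.batch_size < 2:
            raise InvalidInputError("epochs >= 1 and batch_size >= 2 required")

    @classmethod
    def for_scenario(cls, name: str, baseline_loss: str = "mse", **kwargs) -> "ScenarioConfig":
        """Standard configuration for a named scenario."""
        presets = {
            "ORI": dict(loss=baseline_loss, sampler="naive"),
            "BON": dict(loss=baseline_loss, sampler="fixed_ratio"),
            "BLF": dict(loss="clf", sampler="fixed_ratio"),
        }
        if name not in presets:
            raise InvalidInputError(f"scenario must be one of {SCENARIOS}")
        return cls(name=name, **presets[name], **kwargs)


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_sen: list[float] = field(default_factory=list)
    train_spe: list[float] = field(default_factory=list)
    val_sen: list[float] = field(default_factory=list)
    val_spe: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    checkpoint_epoch: int = -1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_sen": self.train_sen,
                "train_spe": self.train_spe,
                "val_sen": self.val_sen,
                "val_spe": self.val_spe,
                "lr": self.lr,
            }
        )


def clr_at(iteration: int, iterations_per_epoch: int, config: CLRConfig) -> float:
    """Triangular2 learning rate at a (0-based) training iteration.

    With half-cycle s = step_size_epochs * iterations_per_epoch:
      cycle = floor(1 + it/(2s)),  x = |it/s - 2*cycle + 1|
      lr = base_lr + (max_lr - base_lr) * max(0, 1 - x) / 2**(cycle - 1)
    """
    if iteration < 0:
        raise InvalidInputError("iteration must be >= 0")
    s = config.step_size_epochs * iterations_per_epoch
    cycle = math.floor(1 + iteration / (2 * s))
    x = abs(iteration / s - 2 * cycle + 1)
    return config.base_lr + (config.max_lr - config.base_lr) * max(0.0, 1.0 - x) / (
        2.0 ** (cycle - 1)
    )


def _sen_spe_at_half(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    c = confusion_at_threshold(scores, labels, 0.5)
    sen = sensitivity(c) if (c.tp + c.fn) else float("nan")
    spe = specificity(c) if (c.tn + c.fp) else float("nan")
    return sen, spe


def train(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    scenario: ScenarioConfig,
    head: HeadConfig = HeadConfig(),
    backbone=None,
    feature_dim: int | None = None,
    clr: CLRConfig = CLRConfig(),
    optimizer: OptimizerConfig = OptimizerConfig(),
    augment_config: AugmentConfig | None = None,
    checkpoint_path: str | Path | None = None,
    log_fn=None,
) -> tuple[Classifier, TrainingHistory]:
    """Train one scenario and return the min-val-loss model plus history.

    ``train_images``/``val_images`` are NHWC float rasters in [0, 1];
    labels are 0/1 vectors.  Validation loss is the scenario's own loss
    computed on the whole validation set at once; training-time SEN/SPE
    monitoring uses threshold 0.5.  Checkpointing keeps the parameters of
    the epoch with the smallest validation loss (also written to
    ``checkpoint_path`` as .npz when given).  Aborts with
    :class:`DivergenceError` on a non-finite loss.
    """
    train_labels = np.asarray(train_labels).astype(np.int64)
    val_labels = np.asarray(val_labels).astype(np.int64)
    if train_labels.size == 0 or val_labels.size == 0:
        raise InvalidInputError("train and validation splits must be non-empty")

    model = (
        build_classifier(head, seed=scenario.seed)
        if backbone is None
        else build_classifier(head, seed=scenario.seed, backbone=backbone,
                              feature_dim=feature_dim or 64)
    )
    opt = Adam(model.net, lr=optimizer.lr, beta1=optimizer.beta1, beta2=optimizer.beta2,
               decay=optimizer.decay)
    loss_fn = make_loss(scenario.loss, scenario.loss_params)

    sampler_rng = np.random.default_rng(scenario.seed + 1_000_003)
    augment_rng = np.random.default_rng(scenario.seed + 2_000_003)

    prevalence = float(train_labels.mean())
    if scenario.sampler == "fixed_ratio":
        frac = scenario.positive_fraction if scenario.positive_fraction is not None else prevalence
        plan = SamplingPlan(batch_size=scenario.batch_size, positive_fraction=frac,
                            seed=scenario.seed)

    history = TrainingHistory()
    best_val = np.inf
    best_state = None
    it = 0
    iterations_per_epoch = None

    for epoch in range(1, scenario.epochs + 1):
        if scenario.sampler == "fixed_ratio":
            schedule = make_epoch(train_labels, plan, rng=sampler_rng)
        else:
            schedule = naive_epoch(train_labels, scenario.batch_size, rng=sampler_rng)
        if iterations_per_epoch is None:
            iterations_per_epoch = max(1, len(schedule))

        epoch_losses = []
        seen_scores, seen_labels = [], []
        lr_now = clr_at(it, iterations_per_epoch, clr)
        for batch_idx in schedule:
            xb = train_images[batch_idx]
            yb = train_labels[batch_idx]
            if augment_config is not None:
                xb = np.stack([augment(im, augment_config, rng=augment_rng) for im in xb])
            scores = model.forward(xb, training=True)
            loss_val = loss_fn.value(scores, yb)
            if not np.isfinite(loss_val):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}, iteration {it}"
                )
            lr_now = clr_at(it, iterations_per_epoch, clr)
            model.backward(loss_fn.grad(scores, yb))
            opt.step(lr=lr_now)
            it += 1
            epoch_losses.append(loss_val)
            seen_scores.append(scores)
            seen_labels.append(yb)

        val_scores = model.predict(val_images)
        val_loss = loss_fn.value(val_scores, val_labels)  # whole set as one batch
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        tr_scores = np.concatenate(seen_scores)
        tr_labels = np.concatenate(seen_labels)
        tr_sen, tr_spe = _sen_spe_at_half(tr_scores, tr_labels)
        v_sen, v_spe = _sen_spe_at_half(val_scores, val_labels)

        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(float(val_loss))
        history.train_sen.append(tr_sen)
        history.train_spe.append(tr_spe)
        history.val_sen.append(v_sen)
        history.val_spe.append(v_spe)
        history.lr.append(lr_now)

        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
            history.checkpoint_epoch = epoch
            if checkpoint_path is not None:
                np.savez(checkpoint_path, **best_state)
        if log_fn is not None:
            log_fn(
                f"epoch={epoch} lr={lr_now:.3e} train_loss={history.train_loss[-1]:.5f} "
                f"val_loss={val_loss:.5f} val_sen={v_sen:.3f} val_spe={v_spe:.3f}"
            )

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
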