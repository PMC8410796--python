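"""The reformed fully-connected classifier head and the backbone contract.

The head follows the architecture that proved effective for binary lesion
classification: two hidden layers of 1024 and 512 units, each as
dense -> ReLU -> batch normalization -> dropout(0.5), followed by a single
sigmoid output unit.  (BN/dropout are listed per hidden layer without a
fixed order in the original design; the ordering here is configurable via
``bn_before_activation``.)

A backbone is anything that maps a batch of HxWx3 rasters to a batch of
fixed-length feature vectors.  At full scale that slot is filled by a
pretrained CNN (e.g. a DenseNet with global average pooling, 1664-dim
features); for desk-scale work and all tests, :func:`build_tiny_backbone`
provides a ~25k-parameter convolutional extractor trainable on CPU in
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import InvalidInputError

__all__ = [
    "HeadConfig",
    "BackboneContract",
    "build_head",
    "build_tiny_backbone",
    "TINY_FEATURE_DIM",
    "Classifier",
]

TINY_FEATURE_DIM = 64


@dataclass(frozen=True)
class HeadConfig:
    hidden_sizes: tuple[int, ...] = (1024, 512)
    dropout_rate: float = 0.5
    use_batchnorm: bool = True
    activation: str = "relu"
    output_activation: str = "sigmoid"
    bn_before_activation: bool = False

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise InvalidInputError("hidden_sizes must be non-empty and positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidInputError("dropout_rate must lie in [0, 1)")
        if self.activation != "relu" or self.output_activation != "sigmoid":
            raise InvalidInputError("only relu hidden / sigmoid output activations are supported")


@dataclass(frozen=True)
class BackboneContract:
    """Descriptor of a feature extractor: name and output dimensionality."""

    name: str
    feature_dim: int
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.feature_dim <= 0:
            raise InvalidInputError("feature_dim must be positive")


def build_head(
    config: HeadConfig, feature_dim: int, rng: np.random.Generator | None = None
) -> nn.Sequential:
    """Classifier head mapping (N, feature_dim) features to (N, 1) scores."""
    if feature_dim <= 0:
        raise InvalidInputError(f"feature_dim must be positive, got {feature_dim}")
    rng = rng or np.random.default_rng(0)
    layers: list[nn.Layer] = []
    prev = feature_dim
    for width in config.hidden_sizes:
        layers.append(nn.Dense(prev, width, rng))
        block: list[nn.Layer] = [nn.ReLU()]
        if config.use_batchnorm:
            bn = nn.BatchNorm1d(width)
            block.insert(0, bn) if config.bn_before_activation else block.append(bn)
        layers.extend(block)
        if config.dropout_rate > 0:
            layers.append(nn.Dropout(config.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))))
        prev = width
    layers.append(nn.Dense(prev, 1, rng))
    layers.append(nn.Sigmoid())
    return nn.Sequential(layers)


def build_tiny_backbone(seed: int = 0) -> nn.Sequential:
    """Small convolutional feature extractor (~25k parameters, 64 features).

    Input rasters are average-pooled 4x then passed through four stride-2
    3x3 convolutions (8, 16, 32, 64 channels) with ReLU, and globally
    average-pooled.  Works for any input at least ~32 px on a side;
    deterministic initialization given ``seed``.
    """
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        [
            nn.AvgPool2d(4),
            nn.Conv2d(3, 8, 3, stride=2, rng=rng),
            nn.ReLU(),
            nn.Conv2d(8, 16, 3, stride=2, rng=rng),
            nn.ReLU(),
            nn.Conv2d(16, 32, 3, stride=2, rng=rng),
            nn.ReLU(),
            nn.Conv2d(32, 64, 3, stride=2, rng=rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
        ]
    )


@dataclass
class Classifier:
    """Backbone + head, trained and evaluated as one network.

    ``forward`` returns a flat vector of sigmoid scores in (0, 1);
    ``backward`` accepts the loss gradient with respect to those scores.
    """

    backbone: nn.Sequential
    head: nn.Sequential
    contract: BackboneContract = field(
        default_factory=lambda: BackboneContract("tiny", TINY_FEATURE_DIM)
    )

    def __post_init__(self):
        self.net = nn.Sequential([self.backbone, self.head])

    def forward(self, images: np.ndarray, training: bool = False) -> np.ndarray:
        out = self.net.forward(images, training=training)
        return out.reshape(-1)

    def backward(self, dscores: np.ndarray) -> None:
        self.net.backward(dscores.reshape(-1, 1))

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode scores, computed in batches."""
        chunks = [
            self.forward(images[i : i + batch_size], training=False)
            for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(chunks) if chunks else np.empty(0)

    def n_params(self) -> int:
        return self.net.n_params()

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(state)

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_classifier(
    head_config: HeadConfig = HeadConfig(), seed: int = 0, backbone: nn.Sequential | None = None,
    feature_dim: int = TINY_FEATURE_DIM,
) -> Classifier:
    """Convenience constructor: tiny backbone + configured head."""
    rng = np.random.default_rng(seed + 1)
    backbone = backbone if backbone is not None else build_tiny_backbone(seed)
    head = build_head(head_config, feature_dim, rng)
    return Classifier(backbone=backbone, head=head)
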