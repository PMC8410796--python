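"""Layers with explicit forward/backward passes.

Every layer exposes ``forward(x, training=False)`` and ``backward(dout)``;
trainable parameters live in ``layer.params`` with matching gradient
buffers in ``layer.grads``.  Convolutions use an im2col formulation so the
heavy lifting is a single BLAS matmul per layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import InvalidInputError


class Layer:
    """Base class; stateless layers leave params/grads empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        if in_features <= 0 or out_features <= 0:
            raise InvalidInputError("Dense features must be positive")
        scale = np.sqrt(2.0 / in_features)  # He init, ReLU networks
        self.params = {
            "W": rng.normal(0.0, scale, size=(in_features, out_features)),
            "b": np.zeros(out_features),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis of (N, F) activations."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        n = dout.shape[0]
        xhat, std = self._xhat, self._std
        self.grads["gamma"][...] = (dout * xhat).sum(axis=0)
        self.grads["beta"][...] = dout.sum(axis=0)
        dxhat = dout * self.params["gamma"]
        # full batch-statistics backward (training-mode normalization)
        return (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std


class Dropout(Layer):
    """Inverted dropout; the mask generator is injected for reproducibility."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise InvalidInputError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Conv2d(Layer):
    """3x3-style convolution, NHWC, 'same' zero padding, integer stride."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        k = kernel_size
        scale = np.sqrt(2.0 / (k * k * in_channels))
        self.params = {
            "W": rng.normal(0.0, scale, size=(k * k * in_channels, out_channels)),
            "b": np.zeros(out_channels),
        }
        self.grads = {kk: np.zeros_like(v) for kk, v in self.params.items()}
        self.k = k
        self.stride = stride
        self.cin = in_channels
        self.cout = out_channels
        self.pad = (k - 1) // 2

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H', W', C, k, k)
        win = win[:, ::s, ::s]
        ho, wo = win.shape[1], win.shape[2]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * c)
        self._cols = cols
        self._xshape = x.shape
        self._out_hw = (ho, wo)
        out = cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, ho, wo, self.cout)

    def backward(self, dout):
        n, h, w, c = self._xshape
        k, s, p = self.k, self.stride, self.pad
        ho, wo = self._out_hw
        dflat = dout.reshape(n * ho * wo, self.cout)
        self.grads["W"][...] = self._cols.T @ dflat
        self.grads["b"][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class AvgPool2d(Layer):
    """Non-overlapping average pooling; trailing rows/cols that do not fill
    a window are cropped."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        k = self.size
        hc, wc = (h // k) * k, (w // k) * k
        self._xshape = x.shape
        xc = x[:, :hc, :wc, :]
        return xc.reshape(n, hc // k, k, wc // k, k, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._xshape
        k = self.size
        dx = np.zeros((n, h, w, c))
        up = np.repeat(np.repeat(dout, k, axis=1), k, axis=2) / (k * k)
        dx[:, : up.shape[1], : up.shape[2], :] = up
        return dx


class GlobalAvgPool(Layer):
    """NHWC feature map -> (N, C) feature vector."""

    def forward(self, x, training=False):
        self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._xshape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def param_items(self):
        """Yield (name, param, grad) triples across all layers."""
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                for name, p, g in layer.param_items():
                    yield f"{i}.{name}", p, g
            else:
                for key in layer.params:
                    yield f"{i}.{type(layer).__name__}.{key}", layer.params[key], layer.grads[key]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.copy() for name, p, _ in self.param_items()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                state[f"{i}.BatchNorm1d.running_mean"] = layer.running_mean.copy()
                state[f"{i}.BatchNorm1d.running_var"] = layer.running_var.copy()
            elif isinstance(layer, Sequential):
                for k, v in layer.state_dict().items():
                    state.setdefault(f"{i}.{k}", v)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.param_items():
            p[...] = state[name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"{i}.BatchNorm1d.running_mean"]
                layer.running_var[...] = state[f"{i}.BatchNorm1d.running_var"]
            elif isinstance(layer, Sequential):
                sub = {
                    k[len(f"{i}.") :]: v for k, v in state.items() if k.startswith(f"{i}.")
                }
                layer.load_state_dict(sub)
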