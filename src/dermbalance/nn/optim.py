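"""Adam optimizer with an externally supplied per-step learning rate."""

from __future__ import annotations

import numpy as np

from .layers import Sequential


class Adam:
    """Adam with bias correction; defaults lr 1e-4, betas (0.9, 0.999).

    ``step(lr=...)`` accepts the current learning rate so a cyclical
    schedule can drive it per iteration.
    """

    def __init__(
        self,
        model: Sequential,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        decay: float = 0.0,
    ):
        self.model = model
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.decay = decay
        self.t = 0
        self._m = {name: np.zeros_like(p) for name, p, _ in model.param_items()}
        self._v = {name: np.zeros_like(p) for name, p, _ in model.param_items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        if self.decay:
            lr = lr / (1.0 + self.decay * self.t)
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, p, g in self.model.param_items():
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
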