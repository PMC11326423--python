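"""Adam optimizer over the layer tree."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    """Adam with L2 weight decay folded into the gradient.

    Matches the common deep-learning formulation: first/second moment
    estimates with bias correction; ``weight_decay * param`` is added to
    each gradient before the moment updates.
    """

    def __init__(
        self,
        model: Layer,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.lr = learning_rate
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for layer in self.model.walk():
            for name, param in layer.params.items():
                grad = layer.grads.get(name)
                if grad is None:
                    continue
                if self.weight_decay:
                    grad = grad + self.weight_decay * param
                key = (id(layer), name)
                m = self._m.setdefault(key, np.zeros_like(param))
                v = self._v.setdefault(key, np.zeros_like(param))
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad**2
                param -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
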