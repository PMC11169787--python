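"""Minimal Adam optimizer over lists of numpy parameter arrays."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias-corrected first/second moments; updates in place."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]
        self._t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list length does not match parameters")
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        correction1 = 1.0 - b1**self._t
        correction2 = 1.0 - b2**self._t
        for p, g, m, v in zip(self.params, grads, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= self.lr * (m / correction1) / (np.sqrt(v / correction2) + self.eps)
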