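"""Adam optimizer updating parameter arrays in place."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        if len(params) != len(grads):
            raise ValueError("params and grads must be parallel lists")
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._scratch = [np.empty_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        alpha = self.lr / b1t
        for p, g, m, v, s in zip(self.params, self.grads, self.m, self.v, self._scratch):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            np.multiply(g, g, out=s)
            s *= 1 - self.b2
            v += s
            np.divide(v, b2t, out=s)
            np.sqrt(s, out=s)
            s += self.eps
            np.divide(m, s, out=s)
            s *= alpha
            p -= s
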