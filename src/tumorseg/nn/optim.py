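"""Optimizers for the NumPy network engine."""

from __future__ import annotations

import numpy as np


class Adamax:
    """Adamax: Adam with an infinity-norm second moment.

    Update (with bias-corrected first moment):
        m <- b1*m + (1-b1)*g
        u <- max(b2*u, |g|)
        p <- p - lr/(1-b1^t) * m/(u+eps)
    """

    def __init__(self, params, learning_rate=0.00025, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = [p for p in params if p.requires_grad]
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._u = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        corr = 1.0 - self.beta1 ** self.t
        for p, m, u in zip(self.params, self._m, self._u):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p.data -= (self.lr / corr) * m / (u + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
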