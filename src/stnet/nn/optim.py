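"""Optimizers."""

from __future__ import annotations

import numpy as np

__all__ = ["RMSprop", "SGD"]


class RMSprop:
    """RMSprop with momentum, following the usual formulation:

        s   <- alpha * s + (1 - alpha) * g^2
        buf <- momentum * buf + g / sqrt(s + eps)
        p   <- p - lr * buf

    with optional decoupled-in-gradient weight decay (g <- g + wd * p).
    """

    def __init__(self, params, lr=5e-4, alpha=0.99, eps=1e-8, momentum=0.9,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.momentum, self.weight_decay = momentum, weight_decay
        self._sq = [np.zeros_like(p.data) for p in self.params]
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, sq, buf in zip(self.params, self._sq, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            sq *= self.alpha
            sq += (1 - self.alpha) * g * g
            buf *= self.momentum
            buf += g / np.sqrt(sq + self.eps)
            p.data -= self.lr * buf

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params, lr=1e-2, momentum=0.0, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
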