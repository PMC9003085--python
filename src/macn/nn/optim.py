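"""First-order optimizers (Adam, SGD with momentum)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.9):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data -= self.lr * b

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
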