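"""First-order optimizers over named parameter/gradient pairs."""

from __future__ import annotations

import numpy as np


class _Optimizer:
    def __init__(self, named_params):
        # list of (name, param_array, grad_array); arrays updated in place
        self.triples = list(named_params)

    def step(self) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, named_params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        super().__init__(named_params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in self.triples]
        self.v = [np.zeros_like(p) for _, p, _ in self.triples]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (name, p, g), m, v in zip(self.triples, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, named_params, lr=1e-2, alpha=0.99, eps=1e-8):
        super().__init__(named_params)
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.v = [np.zeros_like(p) for _, p, _ in self.triples]

    def step(self) -> None:
        for (name, p, g), v in zip(self.triples, self.v):
            v *= self.alpha
            v += (1.0 - self.alpha) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)
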