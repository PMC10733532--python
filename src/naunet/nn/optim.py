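"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(np.float32)


class CosineAnnealingLR:
    """Cosine annealing of the learning rate between base_lr and eta_min.

    lr(t) = eta_min + (base_lr - eta_min) * (1 + cos(pi * t / T_max)) / 2

    ``step()`` advances t by one (called once per epoch).  Past T_max the
    closed form continues, so the rate oscillates with period 2*T_max.
    """

    def __init__(self, optimizer, T_max, eta_min=0.0):
        self.optimizer = optimizer
        self.T_max = int(T_max)
        self.eta_min = float(eta_min)
        self.base_lr = optimizer.lr
        self.t = 0

    def get_lr(self):
        return self.eta_min + (self.base_lr - self.eta_min) * \
            (1 + math.cos(math.pi * self.t / self.T_max)) / 2

    def step(self):
        self.t += 1
        self.optimizer.lr = self.get_lr()
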