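"""Adamax optimizer and a reduce-on-plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np


class Adamax:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bias = 1.0 - self.b1 ** self.t
        for p, m, u in zip(self.params, self.m, self.u):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p.data -= (self.lr / bias) * m / (u + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve (by `factor`) the optimizer lr after `patience` epochs without
    improvement of the monitored metric (lower is better)."""

    def __init__(self, optimizer, factor=0.5, patience=150, min_lr=1e-6,
                 threshold=1e-4):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric):
        if metric < self.best - self.threshold:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.opt.lr
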