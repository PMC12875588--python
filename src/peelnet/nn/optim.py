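"""Optimizers and learning-rate schedules over parameter trees."""

from __future__ import annotations

import numpy as np

from .ptree import ParamTree


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: ParamTree = {}
        self.v: ParamTree = {}
        self.t = 0

    def step(self, params: ParamTree, grads: ParamTree, lr: float | None = None) -> ParamTree:
        lr = self.lr if lr is None else lr
        self.t += 1
        out = {}
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m.get(k)
            if m is None:
                m = np.zeros_like(p)
                self.m[k] = m
                self.v[k] = np.zeros_like(p)
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            out[k] = p - lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
        return out


class SGD:
    def __init__(self, lr: float = 1e-2):
        self.lr = lr

    def step(self, params: ParamTree, grads: ParamTree, lr: float | None = None) -> ParamTree:
        lr = self.lr if lr is None else lr
        return {k: p - lr * grads[k] for k, p in params.items()}


def cosine_lr(
    base_lr: float,
    epoch: int,
    total_epochs: int,
    min_lr: float = 0.0,
    warmup_epochs: int = 0,
) -> float:
    """Cosine-annealed learning rate for the given (0-based) epoch, with an
    optional linear warmup ramp over the first epochs."""
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return base_lr * (epoch + 1) / (warmup_epochs + 1)
    if total_epochs - warmup_epochs <= 1:
        return base_lr
    frac = (epoch - warmup_epochs) / (total_epochs - 1 - warmup_epochs)
    return min_lr + 0.5 * (base_lr - min_lr) * (1 + np.cos(np.pi * frac))
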