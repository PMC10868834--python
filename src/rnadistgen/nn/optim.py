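from __future__ import annotations

import math

import numpy as np

from .core import Parameter


class Adam:
    """Adam with decoupled L2 weight decay and a pluggable LR schedule."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, schedule=None):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.schedule = schedule
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> float:
        self.t += 1
        b1, b2 = self.betas
        lr = self.lr * (self.schedule(self.t) if self.schedule else 1.0)
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= lr * update
        return lr


def warmup_cosine(warmup_steps: int, total_steps: int):
    """Linear warmup followed by cosine decay to zero (factor of base LR)."""

    def factor(t: int) -> float:
        if warmup_steps > 0 and t < warmup_steps:
            return t / warmup_steps
        if total_steps <= warmup_steps:
            return 1.0
        frac = (t - warmup_steps) / (total_steps - warmup_steps)
        frac = min(max(frac, 0.0), 1.0)
        return 0.5 * (1.0 + math.cos(math.pi * frac))

    return factor


def exponential_decay(rate: float):
    """Per-step exponential LR decay factor (e.g. 0.9988 for the score model)."""

    def factor(t: int) -> float:
        return rate ** t

    return factor
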