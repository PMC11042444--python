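"""Optimizers and learning-rate schedules for the numpy network."""

from __future__ import annotations

import numpy as np


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total_steps: int, base_lr: float, warmup: int = 10,
              floor: float = 0.01) -> float:
    """Cosine decay with linear warmup; returns the lr for ``step``."""
    if step < warmup:
        return base_lr * (step + 1) / warmup
    frac = (step - warmup) / max(total_steps - warmup, 1)
    return base_lr * (floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0))))
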