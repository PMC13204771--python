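"""Adam optimizer and a one-cycle learning-rate schedule."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with bias correction (Kingma & Ba). Defaults (0.9, 0.999, 1e-8)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class OneCycleLR:
    """One-cycle schedule: linear warmup to ``max_lr`` over the first
    ``warmup_fraction`` of ``total_steps``, then cosine annealing to
    ``max_lr / final_div``.  ``lr_at(0) < max_lr`` and the peak sits exactly
    at ``warmup_fraction * total_steps``.
    """

    def __init__(self, optimizer: Adam, max_lr: float, total_steps: int,
                 warmup_fraction: float = 0.3, start_div: float = 25.0,
                 final_div: float = 1e4):
        if not 0 < warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")
        self.opt = optimizer
        self.max_lr = max_lr
        self.total_steps = max(int(total_steps), 1)
        self.warmup_steps = max(int(round(warmup_fraction * self.total_steps)), 1)
        self.start_lr = max_lr / start_div
        self.final_lr = max_lr / final_div
        self.step_num = 0
        self.opt.lr = self.lr_at(0)

    def lr_at(self, step: int) -> float:
        if step <= self.warmup_steps:
            frac = step / self.warmup_steps
            return self.start_lr + frac * (self.max_lr - self.start_lr)
        span = max(self.total_steps - self.warmup_steps, 1)
        frac = min((step - self.warmup_steps) / span, 1.0)
        return self.final_lr + 0.5 * (self.max_lr - self.final_lr) * (
            1.0 + np.cos(np.pi * frac))

    def step(self):
        self.step_num += 1
        self.opt.lr = self.lr_at(self.step_num)
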