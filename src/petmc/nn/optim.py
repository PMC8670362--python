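"""Adam optimizer with the stepped exponential learning-rate decay used for
training (decay by a fixed factor every ``decay_every`` batches)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params,
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        lr_decay: float = 1.0,
        decay_every: int = 10,
    ):
        self.params = list(params)
        self.lr0 = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_decay = float(lr_decay)
        self.decay_every = int(decay_every)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        """Learning rate for the upcoming step (decays every decay_every batches)."""
        return self.lr0 * self.lr_decay ** (self.t // self.decay_every)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        lr = self.lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)
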