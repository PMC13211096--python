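"""Optimization: AdamW with decoupled weight decay and a cosine-annealing schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    """AdamW (decoupled weight decay).

    Parameters
    ----------
    params : list of Tensor
        Trainable tensors (``requires_grad=True``).
    lr : float
        Step size.
    betas, eps : Adam moment coefficients and denominator guard.
    weight_decay : float
        Decoupled decay applied multiplicatively to weights each step.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(base_lr: float, step: int, total_steps: int, min_lr: float = 0.0) -> float:
    """Cosine annealing from ``base_lr`` to ``min_lr`` over ``total_steps`` (no restarts)."""
    if total_steps <= 1:
        return base_lr
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + np.cos(np.pi * frac))
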