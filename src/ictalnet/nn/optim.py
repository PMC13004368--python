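"""Optimization utilities: AdamW with decoupled weight decay, gradient clipping."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["AdamW", "clip_grad_norm"]


def clip_grad_norm(params: list[Param], max_norm: float) -> float:
    """Scale gradients in place so the global L2 norm is <= max_norm.

    Returns the pre-clip norm.
    """
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class AdamW:
    """Adaptive-moment optimizer with decoupled (not L2-in-gradient) weight decay."""

    def __init__(self, params: list[Param], lr=5e-4, weight_decay=1e-3,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.data -= self.lr * update
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
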