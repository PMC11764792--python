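"""Adam optimizer and the cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with L2 weight decay folded into the gradient.

    Defaults follow the training recipe: lr 1e-4, betas (0.9, 0.999),
    weight decay 0.01.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
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
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(step: int, total_steps: int, base_lr: float = 1e-4, min_ratio: float = 0.01) -> float:
    """Cosine decay from ``base_lr`` to ``min_ratio * base_lr``.

    ``step`` runs from 0 (returns ``base_lr``) to ``total_steps``
    (returns the floor, 0.01x by default).
    """
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    lo = base_lr * min_ratio
    if total_steps == 0:
        return base_lr
    cos = 0.5 * (1.0 + math.cos(math.pi * step / total_steps))
    return lo + (base_lr - lo) * cos
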