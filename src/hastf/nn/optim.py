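"""Optimizers: AdamW (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Adaptive-moment optimizer with decoupled weight decay.

    Weight decay is applied directly to the parameters (not folded into
    the gradient), i.e. theta <- theta - lr * (m_hat / (sqrt(v_hat)+eps)
    + wd * theta).
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
    ):
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
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
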