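"""Optimisers for the numpy network."""

from __future__ import annotations

import numpy as np

__all__ = ["RMSprop"]


class RMSprop:
    """RMSprop with exponentially-averaged squared gradients.

    Update: ``s <- alpha*s + (1-alpha)*g^2;  p <- p - lr * g / (sqrt(s)+eps)``.
    """

    def __init__(self, params, lr: float = 1e-3, alpha: float = 0.99,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad
            s *= self.alpha
            s += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(s) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
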