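"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["SGD"]


class SGD:
    """v <- mu * v + g;  p <- p - lr * v  (momentum buffers start at zero)."""

    def __init__(self, parameters: list[Tensor], lr: float, momentum: float = 0.9):
        self.parameters = list(parameters)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.data) for p in self.parameters]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.parameters, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v
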