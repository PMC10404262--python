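"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class SGD:
    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v
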