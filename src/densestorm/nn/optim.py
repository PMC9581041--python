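"""ADAM optimizer (Kingma & Ba) for the tensor engine."""

from __future__ import annotations

import numpy as np

from densestorm.nn.tensor import Tensor

__all__ = ["Adam"]


class Adam:
    """First/second-moment adaptive gradient descent.

    Defaults follow the common image-to-image translation recipe:
    lr = 2e-4, beta1 = 0.5 (reduced momentum), beta2 = 0.999.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
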