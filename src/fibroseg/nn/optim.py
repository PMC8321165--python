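"""Adam optimizer over `Param` objects."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, clip_norm: float | None = None):
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        if self.clip_norm is not None:
            sq = sum(float((p.grad.astype(np.float64) ** 2).sum())
                     for p in self.params if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value = (p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
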