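"""Adam optimizer with global-norm gradient clipping."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def global_norm(params: list[Tensor]) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    return float(np.sqrt(total))


def clip_by_global_norm(params: list[Tensor], clip_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``clip_norm``;
    returns the pre-clip norm."""
    norm = global_norm(params)
    if norm > clip_norm:
        factor = clip_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= factor
    return norm


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            p.data -= self.lr * (self.m[k] / bias1) / (
                np.sqrt(self.v[k] / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
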