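"""Adam optimiser and masked binary cross-entropy."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "masked_bce"]


class Adam:
    """Adam with the authors' recommended defaults
    (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clipnorm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clipnorm = clipnorm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.clipnorm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            scale = self.clipnorm / total if total > self.clipnorm else 1.0
        else:
            scale = 1.0
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def masked_bce(probs: Tensor, targets: np.ndarray, mask: np.ndarray,
               eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy of per-step probabilities, averaged over real
    (unmasked) positions only; padded positions contribute nothing.

    ``probs`` may carry a trailing singleton channel; ``targets`` and ``mask``
    are broadcastable numpy arrays of 0/1.
    """
    t = np.asarray(targets, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    if probs.data.ndim == t.ndim + 1 and probs.data.shape[-1] == 1:
        probs = probs.reshape(*probs.shape[:-1])
    p = probs.clip(eps, 1.0 - eps)
    ll = Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log()
    masked = ll * Tensor(m)
    denom = max(float(m.sum()), 1.0)
    return -masked.sum() * (1.0 / denom)
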