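"""Adam optimizer and the binary cross-entropy loss used for training."""

from __future__ import annotations

import numpy as np

from .layers import Param, sigmoid


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean (optionally weighted) binary cross-entropy on logits.

    Works on logits rather than probabilities for numerical stability:
    BCE = softplus(z) − y·z, with gradient w·(σ(z) − y)/N.
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    w = np.ones_like(y) if sample_weights is None else np.asarray(sample_weights)
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(w * (softplus - y * z)))
    grad = w * (sigmoid(z) - y) / len(z)
    return loss, grad
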