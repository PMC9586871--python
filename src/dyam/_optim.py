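"""Minimal Adam optimizer over lists of numpy parameter arrays.

Weight decay is applied pytorch-style: ``l2 * theta`` is added to each
gradient before the moment updates.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.l2 = l2
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.l2 * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_grad(scores: np.ndarray, y: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy loss and its gradient wrt the scores."""
    s = np.clip(scores, 1e-7, 1.0 - 1e-7)
    loss = float(np.mean(weights * -(y * np.log(s) + (1 - y) * np.log(1 - s))))
    grad = weights * (s - y) / (s * (1 - s)) / len(y)
    return loss, grad


def balanced_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights n / (2 * n_class), sklearn's 'balanced' scheme."""
    y = np.asarray(y)
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w
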