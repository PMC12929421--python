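"""Optimizers and the segmentation loss.

Two presets mirror the unified training strategy: SGD with momentum
(lr 0.0025, momentum 0.9, L2 weight decay 5e-4, applied through the
gradient) and AdamW (lr 1e-4, betas (0.9, 0.999), decay 0.01, decoupled —
the decay term never passes through the moment estimates).
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["SGD", "AdamW", "softmax_cross_entropy"]


class SGD:
    """SGD with classical momentum; weight decay is coupled (added to grads)."""

    def __init__(self, params: list[Parameter], lr: float, *,
                 momentum: float = 0.9, weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state(self) -> dict:
        return {"velocity": [v.copy() for v in self._velocity]}

    def load_state(self, state: dict) -> None:
        for v, s in zip(self._velocity, state["velocity"]):
            v[...] = s


class AdamW:
    """Adam with decoupled weight decay: the decay shrinks the weights
    directly and never enters the first/second moment estimates."""

    def __init__(self, params: list[Parameter], lr: float, *,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self._m],
                "v": [v.copy() for v in self._v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        for m, s in zip(self._m, state["m"]):
            m[...] = s
        for v, s in zip(self._v, state["v"]):
            v[...] = s


def softmax_cross_entropy(logits: np.ndarray,
                          target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pixelwise cross-entropy.

    Parameters
    ----------
    logits : (N, K, H, W) float array
    target : (N, H, W) integer class map in [0, K)

    Returns
    -------
    loss : float
    dlogits : gradient of the mean loss w.r.t. the logits
    """
    n, k, h, w = logits.shape
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    count = n * h * w
    onehot_idx = target[:, None, :, :]
    picked = np.take_along_axis(probs, onehot_idx, axis=1)[:, 0]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    dlogits = probs.copy()
    np.put_along_axis(dlogits, onehot_idx,
                      np.take_along_axis(dlogits, onehot_idx, axis=1) - 1.0,
                      axis=1)
    dlogits /= count
    return loss, dlogits.astype(np.float32)
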