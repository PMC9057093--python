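"""Losses returning (scalar loss, gradient w.r.t. predictions)."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; labels are integer class indices."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(p[np.arange(n), labels] + 1e-300).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred.astype(np.float64) - np.asarray(target, dtype=np.float64)
    loss = float(np.mean(diff**2))
    grad = (2.0 * diff / diff.size).astype(pred.dtype)
    return loss, grad
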