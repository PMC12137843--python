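"""Training losses: softmax cross-entropy and mean squared error.

Each loss returns ``(value, grad_wrt_model_output)``; the gradient is
already averaged over the batch so the optimizer step size is
batch-size independent.
"""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Categorical cross-entropy on logits; grad is (p - y)/N."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.sum(onehot * np.log(p + eps)) / n
    return loss, (p - onehot) / n


def mean_squared_error(pred: np.ndarray, target: np.ndarray):
    n = pred.shape[0]
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
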