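"""Softmax cross-entropy with analytic gradient."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``labels`` are integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(logits.dtype)
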