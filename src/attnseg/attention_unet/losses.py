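"""Per-pixel softmax and categorical cross-entropy with analytic gradient."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy over an (N, K, H, W) logit tensor.

    ``targets`` is (N, H, W) integer class indices.  Returns the scalar
    loss and d(loss)/d(logits).
    """
    n, k, h, w = logits.shape
    if targets.shape != (n, h, w):
        raise ValueError(f"targets shape {targets.shape} != {(n, h, w)}")
    probs = softmax(logits, axis=1)
    idx = np.eye(k, dtype=np.float32)[targets].transpose(0, 3, 1, 2)  # one-hot NKHW
    npix = n * h * w
    loss = float(-(idx * np.log(probs + 1e-12)).sum() / npix)
    dlogits = (probs - idx).astype(np.float32) / npix
    return loss, dlogits
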