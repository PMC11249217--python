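"""Binary cross-entropy on logits, numerically stable."""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z)
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    loss = mean( max(z,0) - z*y + log(1+exp(-|z|)) );  dz = (sigmoid(z)-y)/N.
    """
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    y = np.asarray(targets, dtype=np.float64).reshape(-1)
    if z.shape != y.shape:
        raise ValueError(f"logits {z.shape} and targets {y.shape} differ in length")
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / len(z)
    return loss, dz
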