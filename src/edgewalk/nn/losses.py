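"""Loss functions returning (scalar loss, gradient w.r.t. logits/predictions)."""

from __future__ import annotations

import numpy as np


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores.

    ``pos_weight`` rescales the positive-class term, useful when targets
    are sparse. Uses the numerically stable log-sum-exp form.
    """
    t = targets
    # log(1 + e^x) stable
    softplus = np.logaddexp(0.0, logits)
    per = (1.0 - t) * softplus + pos_weight * t * (softplus - logits)
    sig = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
    dper = (1.0 - t) * sig - pos_weight * t * (1.0 - sig)
    n = logits.size
    return float(per.sum() / n), dper / n


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    n = pred.size
    return float((diff**2).sum() / n), 2.0 * diff / n
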