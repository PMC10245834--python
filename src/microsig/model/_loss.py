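"""Focal loss for imbalanced multi-class sample classification.

Focal loss down-weights well-classified examples by a factor (1 - p_t)^gamma,
where p_t is the predicted probability of the true class; at gamma = 0 it
reduces exactly to cross-entropy.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

_P_MIN = 1e-12


def focal_loss(probabilities: np.ndarray, labels: np.ndarray, gamma: float = 2.0) -> float:
    """Mean of -(1 - p_t)^gamma * log(p_t) over samples.

    ``probabilities`` is (n, C) with rows summing to 1; ``labels`` holds class
    indices. True-class probabilities of 0 are clamped at 1e-12 (and logged).
    """
    p = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    pt = p[np.arange(p.shape[0]), labels]
    if np.any(pt <= 0):
        logger.warning("clamping %d zero true-class probabilities", int((pt <= 0).sum()))
        pt = np.clip(pt, _P_MIN, 1.0)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def focal_loss_from_logits(
    logits: np.ndarray, labels: np.ndarray, gamma: float
) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the logits (softmax folded in)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = p.shape[0]
    idx = np.arange(n)
    pt = np.clip(p[idx, labels], _P_MIN, 1.0)
    om = np.clip(1.0 - pt, 0.0, 1.0)
    loss = float(np.mean(-(om ** gamma) * np.log(pt)))
    # dL/dp_t, guarding the gamma < 1 singularity at p_t = 1
    if gamma == 0:
        dl_dpt = -1.0 / pt
    else:
        om_safe = np.maximum(om, _P_MIN)
        dl_dpt = gamma * om_safe ** (gamma - 1.0) * np.log(pt) - om ** gamma / pt
    # dp_t/dz_j = p_t (delta_jt - p_j)
    dz = -p * (dl_dpt * pt)[:, None]
    dz[idx, labels] += dl_dpt * pt
    dz /= n
    return loss, dz
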