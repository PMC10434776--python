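"""Importance-map comparison metrics and the pixel-wise training loss.

Maps are real-valued matrices with entries in [0, 1]; the same type
serves as ground truth Q and prediction P.

* :func:`sigmoid_xent` is the training loss: mean binary cross-entropy
  between sigmoid(logits) and a real-valued target map (the usual
  binary classification loss extended to soft targets in [0, 1]).
* :func:`kl_divergence` normalizes both maps to probability
  distributions and returns sum_i Q_i (log Q_i - log P_i), i.e. the
  divergence of the prediction P from the reference Q.  Zero iff the
  normalized maps coincide; heavily penalizes mass predicted away from
  where the reference puts it.
* :func:`cross_correlation` is the Pearson correlation of the two maps
  over pixels, in [-1, 1]; 1 means one map is a positive affine image
  of the other.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateMapError, HudoptError

__all__ = ["sigmoid_xent", "kl_divergence", "cross_correlation"]

#: Clipping constant keeping the loss finite at saturated predictions.
LOSS_EPS = 1e-7
#: Additive constant used when normalizing maps to distributions.
KL_EPS = 1e-8


def _pair(P, Q) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise HudoptError(f"shape mismatch: {P.shape} vs {Q.shape}")
    if P.size == 0:
        raise HudoptError("empty map")
    return P, Q


def sigmoid_xent(logits, target) -> float:
    """Mean sigmoid cross-entropy of ``logits`` against a soft target map.

    ``L = -(1/N) sum_i [Q_i log P_i + (1 - Q_i) log(1 - P_i)]`` with
    ``P = sigmoid(logits)`` clipped into [eps, 1-eps], eps = 1e-7.
    Minimized over P at P = Q.
    """
    f, Q = _pair(logits, target)
    if Q.min() < 0 or Q.max() > 1:
        raise HudoptError("target map entries must lie in [0, 1]")
    P = np.clip(1.0 / (1.0 + np.exp(-f)), LOSS_EPS, 1.0 - LOSS_EPS)
    return float(-np.mean(Q * np.log(P) + (1.0 - Q) * np.log(1.0 - P)))


def _normalize(M: np.ndarray, name: str) -> np.ndarray:
    if M.min() < 0:
        raise HudoptError(f"{name}: negative entries")
    total = M.sum()
    if total <= 0:
        raise DegenerateMapError(f"{name}: map carries zero mass")
    M = M + KL_EPS
    return M / M.sum()


def kl_divergence(P, Q) -> float:
    """KL divergence of prediction P from reference Q after normalization.

    Both maps are shifted by eps = 1e-8 and normalized to sum 1, then
    ``KL = sum_i (Q_i log Q_i - Q_i log P_i)``.  Non-negative; zero iff
    the normalized maps are identical.
    """
    P, Q = _pair(P, Q)
    p = _normalize(P, "P")
    q = _normalize(Q, "Q")
    return float(np.sum(q * (np.log(q) - np.log(p))))


def cross_correlation(P, Q) -> float:
    """Pearson correlation between two maps over pixels, in [-1, 1].

    Raises :class:`DegenerateMapError` when either map is constant
    (zero variance leaves the coefficient undefined).
    """
    P, Q = _pair(P, Q)
    p = P - P.mean()
    q = Q - Q.mean()
    denom = np.sqrt((p**2).mean()) * np.sqrt((q**2).mean())
    if denom == 0:
        raise DegenerateMapError("constant map: correlation undefined")
    return float((p * q).mean() / denom)
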