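"""Combined binary cross-entropy + soft Dice loss.

loss = w_bce * mean-pixel BCE + w_dice * (1 - (2*sum(p*g) + eps) /
(sum(p) + sum(g) + eps)).  The Dice term is computed once per batch
(not per image); eps = 1 by default, which keeps the term finite and
near zero on all-empty batches.  The gradient is taken with respect to
the logits, using the numerically stable softplus form of BCE.
"""

from __future__ import annotations

import numpy as np


def bce_dice_from_probs(
    probs: np.ndarray,
    truth: np.ndarray,
    bce_weight: float = 1.0,
    dice_weight: float = 1.0,
    eps: float = 1.0,
) -> float:
    """Loss from probability maps (clipped away from {0, 1})."""
    bce, dice = bce_dice_terms(probs, truth, eps)
    return float(bce_weight * bce + dice_weight * dice)


def bce_dice_terms(
    probs: np.ndarray, truth: np.ndarray, eps: float = 1.0
) -> tuple[float, float]:
    """(BCE term, Dice term) from probability maps."""
    p = np.asarray(probs, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"probability map {p.shape} and truth {g.shape} shapes differ")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    pc = np.clip(p, 1e-12, 1.0 - 1e-12)
    bce = float(-np.mean(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)))
    inter = float((p * g).sum())
    sums = float(p.sum() + g.sum())
    dice = 1.0 - (2.0 * inter + eps) / (sums + eps)
    return bce, dice


def loss_and_grad_from_logits(
    z: np.ndarray,
    truth: np.ndarray,
    bce_weight: float = 1.0,
    dice_weight: float = 1.0,
    eps: float = 1.0,
) -> tuple[float, float, float, np.ndarray]:
    """(total, bce, dice, d loss / d logits) for a batch of logit maps."""
    z = np.asarray(z, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    if z.shape != g.shape:
        raise ValueError(f"logit map {z.shape} and truth {g.shape} shapes differ")
    n = z.size
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))), np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    # softplus-form BCE: max(z,0) - z*g + log(1 + exp(-|z|))
    bce = float(np.mean(np.maximum(z, 0.0) - z * g + np.log1p(np.exp(-np.abs(z)))))
    inter = float((p * g).sum())
    sums = float(p.sum() + g.sum())
    dice = 1.0 - (2.0 * inter + eps) / (sums + eps)
    total = bce_weight * bce + dice_weight * dice

    dz_bce = (p - g) / n
    denom = sums + eps
    ddice_dp = -(2.0 * g * denom - (2.0 * inter + eps)) / denom**2
    dz_dice = ddice_dp * p * (1.0 - p)
    dz = bce_weight * dz_bce + dice_weight * dz_dice
    return total, bce, dice, dz.astype(np.float32)
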