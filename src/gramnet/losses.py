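"""Segmentation and classification losses.

The segmentation loss is ``BCE + alpha * DiceTerm`` with ``alpha = 0.2``.
By default the Dice term is the Dice *loss* ``1 - DC`` (minimizing raw Dice
similarity would reward bad masks); set ``dice_as_loss=False`` to add the
similarity itself.  BCE is the standard negative mean binary cross-entropy.

The classification risk is the empirical cross entropy normalized by the
number of classes M (``normalize="classes"``); ``normalize="samples"``
switches to the conventional 1/N mean.  Both normalizations give identical
optimization behaviour under Adam, which is invariant to gradient scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "LossConfig",
    "bce",
    "dice_coefficient",
    "combined_loss",
    "combined_loss_and_dlogits",
    "cross_entropy_risk",
    "cross_entropy_risk_and_dlogits",
]

_EPS = 1e-7


@dataclasses.dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.2          # Dice mixing weight
    dice_as_loss: bool = True   # Dice term is (1 - DC); False adds DC itself
    smooth: float = 1e-6        # stabilizer in the Dice ratio

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")


def _check_shapes(pred, target):
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")


def bce(pred: np.ndarray, target: np.ndarray) -> float:
    """Negative mean binary cross-entropy; 0 iff pred == target (binary)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target)
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log1p(-p)))


def dice_coefficient(pred_mask: np.ndarray, target_mask: np.ndarray,
                     smooth: float = 1e-6) -> float:
    """2|X n Y| / (|X| + |Y|); accepts soft (probability) or hard masks."""
    x = np.asarray(pred_mask, dtype=np.float64)
    y = np.asarray(target_mask, dtype=np.float64)
    _check_shapes(x, y)
    inter = float((x * y).sum())
    return float((2.0 * inter + smooth) / (x.sum() + y.sum() + smooth))


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  cfg: LossConfig = LossConfig()) -> float:
    """BCE + alpha * DiceTerm on a single prediction/target pair."""
    d = dice_coefficient(pred, target, smooth=cfg.smooth)
    term = (1.0 - d) if cfg.dice_as_loss else d
    return bce(pred, target) + cfg.alpha * term


def combined_loss_and_dlogits(probs: np.ndarray, target: np.ndarray,
                              cfg: LossConfig = LossConfig(),
                              ) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. pre-sigmoid logits for a (B, ...) batch.

    BCE is averaged over all elements; the soft Dice term is computed per
    sample and averaged over the batch.  Working in logit space keeps the
    BCE gradient the numerically exact ``(p - t) / n``.
    """
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    _check_shapes(p, t)
    n_total = p.size
    b = p.shape[0]
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    bce_val = float(-np.mean(t * np.log(pc) + (1.0 - t) * np.log1p(-pc)))
    dz = (p - t) / n_total

    pf = p.reshape(b, -1)
    tf = t.reshape(b, -1)
    inter = (pf * tf).sum(axis=1)
    sums = pf.sum(axis=1) + tf.sum(axis=1)
    num = 2.0 * inter + cfg.smooth
    den = sums + cfg.smooth
    dice = num / den
    # dD/dp = (2 t * den - num) / den^2 per sample
    dD = (2.0 * tf * den[:, None] - num[:, None]) / (den ** 2)[:, None]
    sign = -1.0 if cfg.dice_as_loss else 1.0
    term = float(np.mean(1.0 - dice)) if cfg.dice_as_loss else float(np.mean(dice))
    dz = dz + (cfg.alpha * sign / b) * (dD * (pf * (1.0 - pf))).reshape(p.shape)
    return bce_val + cfg.alpha * term, dz


def _check_probs(pred_probs, truth):
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred_probs.shape != truth.shape or pred_probs.ndim != 2:
        raise ValueError("pred_probs and truth must be equal-shaped (N, M)")
    if np.max(np.abs(pred_probs.sum(axis=1) - 1.0)) > 1e-6:
        raise ValueError("rows of pred_probs must sum to 1")
    return pred_probs, truth


def cross_entropy_risk(pred_probs: np.ndarray, truth: np.ndarray,
                       normalize: str = "classes") -> float:
    """Empirical cross-entropy risk of one-hot truths.

    ``normalize="classes"`` divides by the class count M; ``"samples"``
    divides by N.
    """
    pred_probs, truth = _check_probs(pred_probs, truth)
    n, m = pred_probs.shape
    denom = m if normalize == "classes" else n
    p = np.clip(pred_probs, _EPS, 1.0)
    return float(-(truth * np.log(p)).sum() / denom)


def cross_entropy_risk_and_dlogits(logits: np.ndarray, truth: np.ndarray,
                                   normalize: str = "classes",
                                   ) -> tuple[float, np.ndarray]:
    """Risk and gradient w.r.t. softmax logits."""
    from .nn import softmax

    probs = softmax(np.asarray(logits, dtype=np.float64))
    risk = cross_entropy_risk(probs, truth, normalize=normalize)
    n, m = probs.shape
    denom = m if normalize == "classes" else n
    return risk, ((probs - np.asarray(truth, dtype=np.float64)) / denom).astype(np.float32)
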