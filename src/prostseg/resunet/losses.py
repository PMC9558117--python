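"""Segmentation losses returning both the loss and its gradient w.r.t. the
predicted probability map.  An optional per-pixel weight map is supported
(uniform by default)."""

from __future__ import annotations

import numpy as np

__all__ = ["soft_dice_loss", "bce_loss", "get_loss"]


def soft_dice_loss(prob: np.ndarray, target: np.ndarray,
                   weight: np.ndarray | None = None,
                   smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean (1 - soft Dice) over the batch; matches the DSC evaluation metric."""
    p = np.asarray(prob)
    g = np.asarray(target).astype(p.dtype)
    w = np.ones_like(p) if weight is None else np.asarray(weight).astype(p.dtype)
    n = p.shape[0]
    axes = tuple(range(1, p.ndim))
    num = 2.0 * (w * p * g).sum(axis=axes) + smooth
    den = (w * p).sum(axis=axes) + (w * g).sum(axis=axes) + smooth
    loss = float(np.mean(1.0 - num / den))
    shape = (n,) + (1,) * (p.ndim - 1)
    dnum = 2.0 * w * g
    dden = w
    dp = -(dnum * den.reshape(shape) - num.reshape(shape) * dden) / (den.reshape(shape) ** 2) / n
    return loss, dp.astype(p.dtype)


def bce_loss(prob: np.ndarray, target: np.ndarray,
             weight: np.ndarray | None = None,
             eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy on probabilities."""
    p = np.clip(np.asarray(prob), eps, 1.0 - eps)
    g = np.asarray(target).astype(p.dtype)
    w = np.ones_like(p) if weight is None else np.asarray(weight).astype(p.dtype)
    m = p.size
    loss = float(-(w * (g * np.log(p) + (1.0 - g) * np.log(1.0 - p))).sum() / m)
    dp = (-w * (g / p - (1.0 - g) / (1.0 - p)) / m).astype(p.dtype)
    return loss, dp


def dice_bce_loss(prob, target, weight=None):
    l1, g1 = soft_dice_loss(prob, target, weight)
    l2, g2 = bce_loss(prob, target, weight)
    return l1 + l2, g1 + g2


_LOSSES = {"dice": soft_dice_loss, "bce": bce_loss, "dice+bce": dice_bce_loss}


def get_loss(name: str):
    try:
        return _LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(_LOSSES)}") from None
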