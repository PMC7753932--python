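"""Training losses: heatmap MSE and soft-Dice + cross-entropy."""

from __future__ import annotations

import numpy as np


def mse_heatmap_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all voxels; returns (loss, grad wrt pred)."""
    diff = pred - target
    n = diff.size
    return float(np.mean(diff**2)), (2.0 / n) * diff


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def seg_loss(logits: np.ndarray, labels: np.ndarray, ce_weight: float = 1.0,
             dice_weight: float = 1.0, eps: float = 1e-6):
    """Weighted cross-entropy + soft-Dice loss for (C, D, H, W) logits.

    ``labels`` is an integer (D, H, W) map.  Soft Dice is averaged over
    the foreground classes (background overlap is already driven by the
    cross-entropy term and would otherwise dominate the average); the
    gradient is propagated through the softmax analytically.  Returns
    (loss, grad wrt logits).
    """
    c = logits.shape[0]
    n = labels.size
    p = _softmax(logits)
    onehot = np.zeros_like(p)
    flat = labels.reshape(-1)
    onehot.reshape(c, -1)[flat, np.arange(n)] = 1.0

    # cross entropy
    ce = -float(np.mean(np.log(np.maximum(p, eps)) * onehot) * c)
    dL_dp = np.zeros_like(p)
    if ce_weight:
        dL_dp += ce_weight * (-(onehot / np.maximum(p, eps)) / n)

    # soft dice, mean over foreground classes
    fg = slice(1, c) if c > 1 else slice(0, c)
    pf = p.reshape(c, -1)[fg]
    gf = onehot.reshape(c, -1)[fg]
    n_fg = pf.shape[0]
    inter = (pf * gf).sum(axis=1)
    denom = pf.sum(axis=1) + gf.sum(axis=1) + eps
    dice = (2.0 * inter + eps) / denom
    dice_loss = float(1.0 - dice.mean())
    if dice_weight:
        # d(dice_c)/dp_ci = (2 g_ci * denom_c - 2 inter_c) / denom_c^2
        ddice = (2.0 * gf * denom[:, None] - (2.0 * inter + eps)[:, None]) / denom[:, None] ** 2
        dfull = np.zeros_like(p.reshape(c, -1))
        dfull[fg] = -ddice / n_fg
        dL_dp += dice_weight * dfull.reshape(p.shape)

    # back through softmax: dL/dz = p * (dL/dp - sum_c p_c dL/dp_c)
    inner = (p * dL_dp).sum(axis=0, keepdims=True)
    dlogits = p * (dL_dp - inner)
    loss = ce_weight * ce + dice_weight * dice_loss
    return float(loss), dlogits.astype(np.float32)
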