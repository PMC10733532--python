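"""Compound BCE-Dice training loss.

The loss is the sum of (i) binary cross-entropy between the predicted
probability map p and the binary ground truth g, averaged per pixel and then
over the batch, and (ii) a soft Dice loss in which the true-positive /
false-positive / false-negative counts are relaxed to their probabilistic
sums (S = sum p*g, FP~ = sum p*(1-g), FN~ = sum (1-p)*g), computed per image
and averaged over the batch.  The soft relaxation keeps the Dice term
differentiable; hard counts are used only at evaluation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor

logger = logging.getLogger(__name__)

CLAMP_EPS = 1e-7


@dataclass
class LossValue:
    """Scalar loss with its two parts; ``tensor`` carries the autograd graph."""

    total: float
    bce_part: float
    dice_part: float
    tensor: Tensor | None = None

    def backward(self):
        self.tensor.backward()


def bce_dice_loss(pred_probs, gt, eps=CLAMP_EPS, smooth=1.0) -> LossValue:
    """BCE-Dice loss for a batch of probability maps against binary masks.

    ``pred_probs`` is a Tensor or array with values in (0, 1), shape
    (B, 1, H, W) or (B, H, W); ``gt`` is a binary array of the same shape.
    Values at exactly 0 or 1 are clamped to ``eps`` (logged once per call).
    ``smooth`` is the usual additive smoothing of the soft Dice ratio; it
    makes the term exactly 0 for a perfect prediction even when an image has
    an empty mask.
    """
    p = ag.as_tensor(pred_probs)
    g = np.asarray(gt, dtype=np.float32)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if not np.isin(np.unique(g), (0.0, 1.0)).all():
        raise ValueError("ground truth must be strictly binary")
    if p.shape[0] < 1:
        raise ValueError("batch must contain at least one image")
    if (p.data <= 0).any() or (p.data >= 1).any():
        logger.info("bce_dice_loss: clamping predictions to [%g, %g]", eps, 1 - eps)
    p = ag.clip(p, eps, 1.0 - eps)

    # per-pixel mean BCE, then mean over batch == global mean for equal sizes
    bce = ag.mul(ag.tmean(ag.mul(g, ag.log(p)) + ag.mul(1.0 - g, ag.log(p * (-1.0) + 1.0))), -1.0)

    axes = tuple(range(1, len(p.shape)))
    soft_tp = ag.tsum(ag.mul(p, g), axis=axes)                         # S_i
    denom = ag.tsum(p, axis=axes) + ag.as_tensor(g.sum(axis=axes))     # 2S+FP~+FN~
    dice_terms = ag.div(soft_tp * 2.0 + smooth, denom + smooth) * (-1.0) + 1.0
    dice = ag.tmean(dice_terms)

    total = bce + dice
    return LossValue(total=float(total.data), bce_part=float(bce.data),
                     dice_part=float(dice.data), tensor=total)
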