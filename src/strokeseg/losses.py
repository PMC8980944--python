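"""Segmentation losses: binary cross-entropy, soft Dice, and the
deep-supervised mixed loss.

The mixed loss pairs Dice+BCE on the two finest supervision outputs and
Dice alone on the two coarsest:

    L = (L_Dice1 + L_BCE1) + alpha * (L_Dice2 + L_BCE2)
            + beta * (L_Dice3 + L_Dice4)

Dice's smoothing term ``epsilon`` keeps empty-target samples
differentiable (and makes the empty-prediction/empty-target loss exactly
zero).  All functions accept autograd Tensors or plain arrays and return
a scalar Tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autograd import Tensor, as_tensor, clip, log

__all__ = ["LossWeights", "bce_loss", "dice_loss", "mixed_loss"]

_CLAMP = 1e-7


@dataclass
class LossWeights:
    """Mixed-loss coefficients.

    alpha: weight on the step-2 (second-finest) Dice+BCE term.
    beta: joint weight on the step-3/step-4 Dice terms.
    epsilon: Dice smoothing constant in (0, 1].

    Defaults down-weight the auxiliary heads by depth (alpha=0.5,
    beta=0.25); epsilon=1 is the common "smooth" choice.
    """

    alpha: float = 0.5
    beta: float = 0.25
    epsilon: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")


def _check_shapes(pred: Tensor, target: Tensor):
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")


def bce_loss(pred, target, clamp: float = _CLAMP) -> Tensor:
    """Mean binary cross-entropy, -(1/N) sum[y log p + (1-y) log(1-p)].

    Probabilities are clamped ``clamp`` away from 0 and 1 before the
    logarithms; the result is the standard nonnegative mean NLL.
    """
    pred, target = as_tensor(pred), as_tensor(target)
    _check_shapes(pred, target)
    p = clip(pred, clamp, 1.0 - clamp)
    ll = target * log(p) + (1.0 - target) * log(1.0 - p)
    return -ll.mean()


def dice_loss(pred, target, epsilon: float = 1.0) -> Tensor:
    """Soft Dice loss, 1 - (2 sum(p*y) + eps) / (sum(p) + sum(y) + eps).

    For batched ``N x ...`` input the Dice is taken over all pixels of
    each sample and averaged across the batch; a single 2D/3D map is one
    sample.  An empty prediction against an empty target scores exactly
    0 thanks to ``epsilon``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pred, target = as_tensor(pred), as_tensor(target)
    _check_shapes(pred, target)
    if pred.ndim >= 4:  # batched: reduce per sample, then average
        axes = tuple(range(1, pred.ndim))
        inter = (pred * target).sum(axis=axes)
        denom = pred.sum(axis=axes) + target.sum(axis=axes)
        return (1.0 - (2.0 * inter + epsilon) / (denom + epsilon)).mean()
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum()
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def mixed_loss(outputs, target, weights: LossWeights | None = None) -> Tensor:
    """Deep-supervised mixed loss over the four step outputs.

    ``outputs`` is the step-ordered list [step1 (finest) .. step4
    (coarsest)], each at the target's full resolution.
    """
    if len(outputs) != 4:
        raise ValueError(f"expected 4 supervision outputs, got {len(outputs)}")
    w = weights or LossWeights()
    target = as_tensor(target)
    s1, s2, s3, s4 = (as_tensor(o) for o in outputs)
    eps = w.epsilon
    term1 = dice_loss(s1, target, eps) + bce_loss(s1, target)
    term2 = dice_loss(s2, target, eps) + bce_loss(s2, target)
    term34 = dice_loss(s3, target, eps) + dice_loss(s4, target, eps)
    return term1 + w.alpha * term2 + w.beta * term34
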