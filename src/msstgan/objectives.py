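"""Loss terms for the semi-supervised adversarial segmentation objective.

All terms are mean-reduced negative log-likelihoods (batch-size invariant)
with probabilities clamped to [1e-7, 1 - 1e-7] so every term is finite and
non-negative:

    L_D        = mean(-log(1 - D(x, yhat))) + mean(-log(D(x, y)))
    L_Adv      = mean(-log(D(x, yhat)))
    L_BCE      = mean(-[y log yhat + (1-y) log(1-yhat)])
    L_Dice     = 1 - (2 sum(y yhat) + eps) / (sum y + sum yhat + eps)
    L_joint    = L_BCE + L_Dice + L_Adv
    L_sup      = L_joint + L_D          (labeled data)
    L_unsup    = L_Adv                  (unlabeled data)
    L_semi     = L_sup + L_unsup

The Dice denominator is the soft sum-of-areas form (a soft prediction has
no set union) with smoothing eps = 1e-6, computed per image then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import Tensor, as_tensor

__all__ = [
    "bce_loss", "dice_loss", "adversarial_loss", "discriminator_loss",
    "joint_loss", "semi_losses", "LossWeights",
]

_CLAMP = 1e-7
_DICE_EPS = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Optional re-weighting of the joint-loss terms (all 1 by default)."""

    bce: float = 1.0
    dice: float = 1.0
    adv: float = 1.0


def _check_shapes(pred: Tensor, target: Tensor) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")


def bce_loss(pred, target) -> Tensor:
    """Pixel-wise binary cross entropy between soft prediction and mask."""
    pred, target = as_tensor(pred), as_tensor(target)
    _check_shapes(pred, target)
    p = pred.clamp(_CLAMP, 1.0 - _CLAMP)
    return -(target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()


def dice_loss(pred, target) -> Tensor:
    """Soft Dice loss, per image then batch-averaged; in [0, 1]."""
    pred, target = as_tensor(pred), as_tensor(target)
    _check_shapes(pred, target)
    axes = tuple(range(1, pred.ndim)) if pred.ndim > 1 else (0,)
    inter = (pred * target).sum(axis=axes)
    areas = pred.sum(axis=axes) + target.sum(axis=axes)
    dice = (2.0 * inter + _DICE_EPS) / (areas + _DICE_EPS)
    return (1.0 - dice).mean()


def adversarial_loss(fake_scores) -> Tensor:
    """-log D over patch scores of (image, prediction) pairs; low when the
    discriminator is fooled into calling predictions real."""
    s = as_tensor(fake_scores).clamp(_CLAMP, 1.0 - _CLAMP)
    return -(s.log()).mean()


def discriminator_loss(fake_scores=None, real_scores=None) -> Tensor:
    """BCE over patches: prediction pairs labeled 0, ground-truth pairs 1.

    On unlabeled batches there are no ground-truth pairs; the real term is
    then omitted (fake-only update).
    """
    if fake_scores is None and real_scores is None:
        raise ValueError("discriminator loss needs fake and/or real scores")
    total = None
    if fake_scores is not None:
        f = as_tensor(fake_scores).clamp(_CLAMP, 1.0 - _CLAMP)
        total = -((1.0 - f).log()).mean()
    if real_scores is not None:
        r = as_tensor(real_scores).clamp(_CLAMP, 1.0 - _CLAMP)
        term = -(r.log()).mean()
        total = term if total is None else total + term
    return total


def joint_loss(pred, target, fake_scores, weights: LossWeights | None = None) -> Tensor:
    """Generator loss on labeled data: BCE + Dice + adversarial (unweighted
    by default)."""
    w = weights or LossWeights()
    return (w.bce * bce_loss(pred, target)
            + w.dice * dice_loss(pred, target)
            + w.adv * adversarial_loss(fake_scores))


def semi_losses(supervised, unsupervised=None):
    """Compose the semi-supervised objective.

    Returns ``(supervised, unsupervised, total)``; with no unlabeled part
    the total reduces to the supervised loss exactly.
    """
    if supervised is None:
        raise ValueError("the semi-supervised protocol requires labeled data")
    supervised = as_tensor(supervised)
    if unsupervised is None:
        unsupervised = Tensor(0.0)
    else:
        unsupervised = as_tensor(unsupervised)
    return supervised, unsupervised, supervised + unsupervised
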