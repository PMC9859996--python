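"""Multi-task loss: classification BCE plus segmentation BCE + soft Dice.

The segmentation loss on one image is

    L_seg(y, t) = L_BCE(y, t) + L_Dice(y, t),
    L_Dice(y, t) = 1 - (2 * sum(y*t) + 1) / (sum(y) + sum(t) + 1),

with y the predicted per-pixel probability map and t the binary ground
truth. The "+1" smoothing makes the Dice term well-behaved on lesion-free
images (empty-vs-empty is a perfect 0 loss). The classification term is
binary cross-entropy on the image-level normal/abnormal logit. By default
BCE is reduced by the pixel mean rather than the raw pixel sum so loss
magnitudes are comparable across image sizes and with the Dice term; the
summed form is available via ``reduction="sum"``.

Two parallel implementations are provided: plain-numpy functions
(`bce_loss`, `dice_loss`) for evaluation and testing, and autodiff
versions inside `total_loss` used by the training loop. A consistency test
pins them to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = ["LossConfig", "bce_loss", "dice_loss", "total_loss"]

_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Weights and policies of the multi-task loss.

    cls_weight: weight of the classification BCE term (segmentation terms
    have weight 1). dice_smooth is the additive smoothing constant of the
    Dice term (1.0 in the reference formulation). When
    apply_seg_loss_to_normals is true, lesion-free images contribute a
    segmentation loss against an all-zero mask — i.e. normal images also
    optimize the decoder.
    """

    cls_weight: float = 1.0
    dice_smooth: float = 1.0
    apply_seg_loss_to_normals: bool = True
    reduction: str = "mean"

    def validate(self) -> None:
        if self.cls_weight < 0:
            raise ValueError("cls_weight must be non-negative")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def bce_loss(y: np.ndarray, t: np.ndarray, reduction: str = "mean") -> float:
    """Binary cross-entropy between a probability grid and a binary grid."""
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {t.shape}")
    yc = np.clip(y, _EPS, 1.0 - _EPS)
    ll = -(t * np.log(yc) + (1.0 - t) * np.log(1.0 - yc))
    if reduction == "mean":
        return float(ll.mean())
    if reduction == "sum":
        return float(ll.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def dice_loss(y: np.ndarray, t: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss: 1 - (2*sum(y t)+s) / (sum(y)+sum(t)+s)."""
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {t.shape}")
    num = 2.0 * (y * t).sum() + smooth
    den = y.sum() + t.sum() + smooth
    return float(1.0 - num / den)


def _dice_loss_tensor(probs: Tensor, t: np.ndarray, smooth: float) -> Tensor:
    """Batched soft Dice on autodiff tensors; mean over images.

    probs: (N, H, W) probabilities; t: (N, H, W) binary.
    """
    n = probs.shape[0]
    flat = ag.reshape(probs, (n, -1))
    tf = Tensor(t.reshape(n, -1).astype(np.float32))
    inter = ag.tsum(flat * tf, axis=1)
    sums = ag.tsum(flat, axis=1) + ag.tsum(tf, axis=1)
    dice = 1.0 - (2.0 * inter + smooth) / (sums + smooth)
    return ag.tmean(dice)


def total_loss(class_logit: Tensor | None, seg_logits: Tensor,
               labels: np.ndarray, masks: np.ndarray,
               config: LossConfig = LossConfig()) -> tuple[Tensor, dict]:
    """Combined loss over a batch; returns (total, component floats).

    class_logit: (N,) image-level logits, or None for a gate-free
    baseline network. seg_logits: (N, H, W). labels: (N,) in {0, 1}
    (1 = abnormal). masks: (N, H, W) binary.
    """
    config.validate()
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0=normal, 1=abnormal)")
    masks = np.asarray(masks)
    if masks.shape != seg_logits.shape:
        raise ValueError("mask / segmentation shape mismatch")
    uniq = np.unique(masks)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("masks must be binary")

    components: dict[str, float] = {}
    if config.apply_seg_loss_to_normals:
        keep = np.ones(len(labels), dtype=bool)
    else:
        keep = labels.astype(bool)
    total: Tensor | None = None
    if keep.any():
        # segmentation branch; slicing the batch keeps the graph intact by
        # computing losses only on the kept subset's logits
        if keep.all():
            seg_sel, mask_sel = seg_logits, masks
        else:
            idx = np.where(keep)[0]
            seg_sel = _take_batch(seg_logits, idx)
            mask_sel = masks[idx]
        seg_bce = ag.bce_with_logits(seg_sel,
                                     mask_sel.astype(np.float32),
                                     reduction=config.reduction)
        probs = ag.sigmoid(seg_sel)
        seg_dice = _dice_loss_tensor(probs, mask_sel, config.dice_smooth)
        components["seg_bce"] = seg_bce.item()
        components["seg_dice"] = seg_dice.item()
        total = seg_bce + seg_dice
    else:
        components["seg_bce"] = 0.0
        components["seg_dice"] = 0.0
    if class_logit is not None:
        cls = ag.bce_with_logits(class_logit, labels.astype(np.float32))
        components["cls_bce"] = cls.item()
        cls_term = config.cls_weight * cls
        total = cls_term if total is None else total + cls_term
    if total is None:
        total = Tensor(np.float32(0.0))
    components["total"] = total.item()
    return total, components


def _take_batch(x: Tensor, idx: np.ndarray) -> Tensor:
    """Differentiable batch-axis gather."""
    out = ag._make(x.data[idx], (x,))
    if out.requires_grad:
        def bwd(g):
            gx = np.zeros_like(x.data)
            gx[idx] = g
            x._accumulate(gx)
        out._backward = bwd
    return out
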