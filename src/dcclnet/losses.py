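"""Loss terms of the semi-supervised framework.

Supervised branches use the even mix ``0.5 * (CE + soft Dice)`` against
ground truth.  Unsupervised terms:

* auxiliary-decoder consistency — mean of the three MSEs between the main
  decoder's and each auxiliary decoder's probability maps (gradients flow
  into both);
* teacher consistency — MSE between the student's probabilities on the
  clean input and the (gradient-detached) teacher's on the noised input;
* co-training — symmetric cross-pseudo-label Dice: each network is
  supervised by the hard, detached argmax map of the other.

The total objective is
``L = L_sup^u + L_sup^su + lambda1 * (L_aux + L_teacher) + lambda2 * L_cotrain``
with ramped weights supplied by :mod:`dcclnet.dynamics`.

All losses accept autodiff tensors (differentiable) or plain arrays, and
operate on softmax probabilities, never logits.  Soft Dice includes the
background class; the evaluation metrics exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbones import SegOutput

DICE_EPS = 1e-5


class ConfigError(ValueError):
    pass


@dataclass
class LossBreakdown:
    """Per-term record of one training step; all entries are floats."""

    sup_u: float = 0.0
    sup_su: float = 0.0
    unsup_aux: float = 0.0
    unsup_teacher: float = 0.0
    unsup_cotrain: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    total: float = 0.0

    FIELDS = ("sup_u", "sup_su", "unsup_aux", "unsup_teacher", "unsup_cotrain",
              "lambda1", "lambda2", "total")

    def as_row(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


def _scalar(x) -> float:
    return x.item() if isinstance(x, Tensor) else float(x)


def _class_axis(shape: tuple[int, ...]) -> int:
    if len(shape) == 3:
        return 0
    if len(shape) == 4:
        return 1
    raise ValueError(f"expected (C,H,W) or (N,C,H,W), got {shape}")


def one_hot(indices: np.ndarray, n_classes: int,
            dtype=np.float32) -> np.ndarray:
    """Integer label map -> one-hot with the class axis in network layout."""
    indices = np.asarray(indices)
    eye = np.eye(n_classes, dtype=dtype)
    oh = eye[indices]  # (..., C)
    if indices.ndim == 2:
        return oh.transpose(2, 0, 1)
    if indices.ndim == 3:
        return oh.transpose(0, 3, 1, 2)
    raise ValueError(f"expected 2D or 3D label map, got shape {indices.shape}")


def dice_loss(probs, target_onehot, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss, averaged over all classes including background."""
    probs = ad.as_tensor(probs)
    target_onehot = np.asarray(target_onehot)
    if probs.shape != target_onehot.shape:
        raise ValueError(
            f"shape mismatch: probs {probs.shape} vs target {target_onehot.shape}")
    caxis = _class_axis(probs.shape)
    reduce_axes = tuple(i for i in range(probs.ndim) if i != caxis)
    inter = ad.sum_(probs * target_onehot, axis=reduce_axes)
    p_sum = ad.sum_(probs, axis=reduce_axes)
    t_sum = target_onehot.sum(axis=reduce_axes)
    dice = (2.0 * inter + eps) * ((p_sum + t_sum + eps) ** -1.0)
    return 1.0 - ad.mean(dice)


def ce_loss(probs, target_indices) -> Tensor:
    """Mean pixelwise negative log-probability of the target class."""
    probs = ad.as_tensor(probs)
    target = np.asarray(target_indices)
    caxis = _class_axis(probs.shape)
    n_classes = probs.shape[caxis]
    if target.max(initial=0) >= n_classes:
        raise IndexError(
            f"target label {int(target.max())} >= number of classes {n_classes}")
    if probs.ndim == 3:
        hh, ww = np.meshgrid(np.arange(probs.shape[1]), np.arange(probs.shape[2]),
                             indexing="ij")
        picked = probs[(target, hh, ww)]
    else:
        n, _, h, w = probs.shape
        nn_, hh, ww = np.meshgrid(np.arange(n), np.arange(h), np.arange(w),
                                  indexing="ij")
        picked = probs[(nn_, target, hh, ww)]
    return -ad.mean(ad.log(picked, eps=1e-12))


def supervised_loss(output: SegOutput, y: np.ndarray) -> Tensor:
    """``0.5 * (CE + Dice)`` against an integer label map."""
    probs = output.probs
    caxis = _class_axis(probs.shape)
    target_oh = one_hot(y, probs.shape[caxis])
    return 0.5 * (ce_loss(probs, y) + dice_loss(probs, target_oh))


def mse(a, b) -> Tensor:
    a = ad.as_tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return ad.mean((a - b) ** 2.0)


def aux_consistency_loss(main: SegOutput, auxes: Sequence[SegOutput]) -> Tensor:
    """Mean MSE between the main and each auxiliary probability map."""
    if len(auxes) != 3:
        raise ConfigError(f"expected 3 auxiliary decoders, got {len(auxes)}")
    total = None
    for aux in auxes:
        term = mse(main.probs, aux.probs)
        total = term if total is None else total + term
    return total * (1.0 / 3.0)


def teacher_consistency_loss(student: SegOutput, teacher: SegOutput) -> Tensor:
    """MSE against the teacher's detached probabilities."""
    return mse(student.probs, teacher.probs.detach())


def make_pseudo_label(output: SegOutput) -> np.ndarray:
    """Hard one-hot argmax map, gradient-detached; ties -> lowest class."""
    probs = output.probs.data if isinstance(output.probs, Tensor) else np.asarray(output.probs)
    caxis = _class_axis(probs.shape)
    idx = probs.argmax(axis=caxis)
    return one_hot(idx, probs.shape[caxis])


def cotrain_loss(out_u: SegOutput, out_su: SegOutput) -> Tensor:
    """Symmetric cross-pseudo-label Dice between the two backbones."""
    if out_u.probs.shape != out_su.probs.shape:
        raise ValueError(
            f"shape mismatch: {out_u.probs.shape} vs {out_su.probs.shape}")
    pseudo_su = make_pseudo_label(out_su)
    pseudo_u = make_pseudo_label(out_u)
    return dice_loss(out_u.probs, pseudo_su) + dice_loss(out_su.probs, pseudo_u)


def total_loss(sup_u=0.0, sup_su=0.0, unsup_aux=0.0, unsup_teacher=0.0,
               unsup_cotrain=0.0, *, lambda1: float, lambda2: float):
    """Weighted sum of all terms; disabled components contribute exactly 0.

    Returns ``(total, LossBreakdown)`` where ``total`` keeps whatever type
    (tensor or float) the parts carry so it can be backpropagated, and the
    breakdown records plain floats.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ConfigError("loss weights must be nonnegative")
    total = sup_u + sup_su + lambda1 * (unsup_aux + unsup_teacher) \
        + lambda2 * unsup_cotrain
    breakdown = LossBreakdown(
        sup_u=_scalar(sup_u), sup_su=_scalar(sup_su),
        unsup_aux=_scalar(unsup_aux), unsup_teacher=_scalar(unsup_teacher),
        unsup_cotrain=_scalar(unsup_cotrain),
        lambda1=float(lambda1), lambda2=float(lambda2), total=_scalar(total))
    return total, breakdown
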