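"""Training losses.

Raw (un-mixed) patches are supervised at several decoder resolutions with a
sum of cross-entropy and soft Dice, the contribution of resolution ``d``
weighted by ``1/2**d`` (finest resolution d=0, unnormalized weights):

    Loss_raw = sum_{d=0}^{l-1} (1/2**d) * [ CE(x_d, y_d) + Dice(x_d, y_d) ]

MixUp-synthesized patches carry soft labels and are supervised with plain
cross-entropy at the finest resolution only — the Dice term and deep
supervision are omitted because soft labels have no meaningful per-class
overlap.

The soft Dice is computed per class over the whole batch and averaged over
all classes (background included) with smoothing eps = 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "one_hot",
    "dice_loss",
    "cross_entropy_loss",
    "downsample_labels",
    "deep_supervision_loss",
    "mixup_loss",
    "DeepSupervisionTargets",
    "LossBreakdown",
]

DICE_EPS = 1e-5


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, D, H, W) integer labels -> (N, C, D, H, W) one-hot float32."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:],
                   dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


@dataclass
class DeepSupervisionTargets:
    """Per-resolution label arrays, finest (d=0) first."""

    labels_per_resolution: list[np.ndarray]

    @property
    def l(self) -> int:
        return len(self.labels_per_resolution)


@dataclass
class LossBreakdown:
    total: Tensor
    ce_per_resolution: list[float] = field(default_factory=list)
    dice_per_resolution: list[float] = field(default_factory=list)
    mixup_ce: float | None = None

    @property
    def total_value(self) -> float:
        return self.total.item()


def dice_loss(probs: Tensor, target_onehot: np.ndarray,
              eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss, 1 - mean over classes of the batch-pooled Dice."""
    t = np.asarray(target_onehot, dtype=np.float32)
    if t.shape != probs.data.shape:
        raise ValueError(
            f"target shape {t.shape} != probs shape {probs.data.shape}")
    axes = (0,) + tuple(range(2, probs.data.ndim))
    inter = (probs * t).sum(axis=axes)
    denom = probs.sum(axis=axes) + t.sum(axis=axes)
    dice_per_class = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice_per_class.mean()


def cross_entropy_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; hard integer or soft per-class targets."""
    logits = nn.tensor(logits)
    target = np.asarray(target)
    if target.ndim == logits.data.ndim - 1:  # hard labels
        target = one_hot(target, logits.data.shape[1])
    return nn.softmax_cross_entropy(logits, target)


def downsample_labels(labels: np.ndarray,
                      strides_per_head: list[tuple[int, int, int]]
                      ) -> DeepSupervisionTargets:
    """Nearest-neighbor (strided-slicing) label downsampling per head.

    ``labels`` is (N, D, H, W); head 0 must have stride (1,1,1) and returns
    the labels unchanged.
    """
    labels = np.asarray(labels)
    per_res = []
    for sz, sy, sx in strides_per_head:
        for ax, s in zip(labels.shape[1:], (sz, sy, sx)):
            if ax % s:
                raise ValueError(
                    f"label shape {labels.shape[1:]} not divisible by stride "
                    f"({sz},{sy},{sx})")
        per_res.append(labels[:, ::sz, ::sy, ::sx])
    return DeepSupervisionTargets(per_res)


def deep_supervision_loss(logits_list: list[Tensor],
                          targets: DeepSupervisionTargets,
                          n_classes: int | None = None) -> LossBreakdown:
    """CE + Dice summed over resolutions with weights 1/2**d."""
    if len(logits_list) != targets.l:
        raise ValueError(
            f"{len(logits_list)} logit arrays but {targets.l} target resolutions")
    n_classes = n_classes or logits_list[0].data.shape[1]
    total = None
    ces, dices = [], []
    for d, (logits, lab) in enumerate(zip(logits_list, targets.labels_per_resolution)):
        t = one_hot(lab, n_classes)
        ce = nn.softmax_cross_entropy(logits, t)
        dc = dice_loss(nn.softmax(logits, axis=1), t)
        w = 0.5 ** d
        term = w * (ce + dc)
        total = term if total is None else total + term
        ces.append(ce.item())
        dices.append(dc.item())
    return LossBreakdown(total=total, ce_per_resolution=ces,
                         dice_per_resolution=dices)


def mixup_loss(logits_finest: Tensor, y_mix: np.ndarray) -> Tensor:
    """Cross-entropy against soft MixUp labels; no Dice, no resolution sum."""
    return cross_entropy_loss(logits_finest, np.asarray(y_mix, dtype=np.float32))
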