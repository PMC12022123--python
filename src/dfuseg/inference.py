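"""Sliding-window prediction with flip test-time augmentation and
cross-fold ensemble averaging.

Windows tile the (padded) volume with a configurable step fraction; each
window's softmax probabilities are accumulated under an optional Gaussian
center weighting and normalized by the accumulated weight, so overlapping
windows blend smoothly and every probability volume sums to 1 per voxel.
TTA averages predictions over all subsets of the configured flip axes, and
the ensemble averages the TTA outputs of several models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import nn
from .preprocessing import CropRecord
from .volume import Volume

__all__ = [
    "InferenceConfig",
    "sliding_window_predict",
    "tta_predict",
    "ensemble_predict",
    "probabilities_to_labels",
    "restore_to_original_grid",
    "compute_window_starts",
    "gaussian_window",
]


@dataclass
class InferenceConfig:
    patch_size: tuple[int, int, int] = (56, 224, 160)
    window_step_fraction: float = 0.5
    gaussian_weighting: bool = True
    tta_flip_axes: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if not 0 < self.window_step_fraction <= 1:
            raise ValueError("window_step_fraction must be in (0, 1]")


def compute_window_starts(size: int, patch: int, step_fraction: float
                          ) -> list[int]:
    """Start indices tiling [0, size) with stride step_fraction*patch; the
    last window is clamped to the boundary so every voxel is covered."""
    if size <= patch:
        return [0]
    step = max(1, int(round(patch * step_fraction)))
    starts = list(range(0, size - patch + 1, step))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def gaussian_window(patch_size, sigma_fraction: float = 0.125) -> np.ndarray:
    """Separable Gaussian center weighting, sigma = patch/8 per axis."""
    ws = []
    for n in patch_size:
        x = np.arange(n) - (n - 1) / 2.0
        sigma = max(n * sigma_fraction, 1.0)
        ws.append(np.exp(-0.5 * (x / sigma) ** 2))
    w = ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    return (w / w.max()).astype(np.float32)


def _softmax_np(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _forward_probs(network, patch: np.ndarray) -> np.ndarray:
    """(C, d, h, w) patch -> (n_classes, d, h, w) softmax of the finest head."""
    with nn.no_grad():
        logits = network(patch[None])[0].data[0]
    return _softmax_np(logits, axis=0)


def _pad_to_patch(image: np.ndarray, patch_size) -> tuple[np.ndarray, list]:
    pads = [(0, 0)]
    for ax, p in enumerate(patch_size):
        short = max(0, p - image.shape[ax + 1])
        pads.append((short // 2, short - short // 2))
    return np.pad(image, pads), pads


def sliding_window_predict(network, image: np.ndarray,
                           cfg: InferenceConfig) -> np.ndarray:
    """Tile the volume, average window softmax probabilities.

    ``image`` is (C, D, H, W) preprocessed exactly as in training; the
    network may be a BasicSegNet (all channels as one input) or a DFUNet
    (channel 0 primary, the rest secondary).  Returns (n_classes, D, H, W)
    probabilities summing to 1 per voxel.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 4:
        raise ValueError("image must be (C, D, H, W)")
    orig_shape = image.shape[1:]
    image, pads = _pad_to_patch(image, cfg.patch_size)
    shape = image.shape[1:]

    is_dual = _takes_two_inputs(network)

    weight = (gaussian_window(cfg.patch_size) if cfg.gaussian_weighting
              else np.ones(cfg.patch_size, dtype=np.float32))
    n_classes = network.spec.n_classes
    acc = np.zeros((n_classes,) + shape, dtype=np.float64)
    wacc = np.zeros(shape, dtype=np.float64)
    starts = [compute_window_starts(shape[i], cfg.patch_size[i],
                                    cfg.window_step_fraction)
              for i in range(3)]
    for z, y, x in itertools.product(*starts):
        sl = (slice(None), slice(z, z + cfg.patch_size[0]),
              slice(y, y + cfg.patch_size[1]), slice(x, x + cfg.patch_size[2]))
        patch = image[sl]
        if is_dual:
            with nn.no_grad():
                logits = network(patch[None, :1], patch[None, 1:])[0].data[0]
            probs = _softmax_np(logits, axis=0)
        else:
            probs = _forward_probs(network, patch)
        acc[sl] += probs * weight
        wacc[sl[1:]] += weight
    if wacc.min() <= 0:
        raise RuntimeError("sliding window left uncovered voxels")
    probs = (acc / wacc).astype(np.float32)
    # renormalize to remove float accumulation error
    probs /= probs.sum(axis=0, keepdims=True)
    unpad = tuple(slice(p[0], p[0] + s) for p, s in zip(pads[1:], orig_shape))
    return probs[(slice(None),) + unpad]


def _takes_two_inputs(network) -> bool:
    return hasattr(network, "encoder2")


def tta_predict(network, image: np.ndarray, cfg: InferenceConfig
                ) -> np.ndarray:
    """Average sliding-window predictions over every subset of the
    configured flip axes (flip input, predict, flip back)."""
    axes = tuple(cfg.tta_flip_axes)
    variants = [c for r in range(len(axes) + 1)
                for c in itertools.combinations(axes, r)]
    out = None
    for combo in variants:
        flip_axes = tuple(a + 1 for a in combo)  # skip channel axis
        x = np.flip(image, axis=flip_axes) if combo else image
        p = sliding_window_predict(network, np.ascontiguousarray(x), cfg)
        if combo:
            p = np.flip(p, axis=flip_axes)
        out = p if out is None else out + p
    return (out / len(variants)).astype(np.float32)


def ensemble_predict(networks, image: np.ndarray, cfg: InferenceConfig
                     ) -> np.ndarray:
    """Arithmetic mean of per-model TTA probability volumes."""
    networks = list(networks)
    if not networks:
        raise ValueError("ensemble needs at least one model")
    n_classes = {net.spec.n_classes for net in networks}
    if len(n_classes) != 1:
        raise ValueError(f"incompatible class counts across ensemble: {n_classes}")
    out = None
    for net in networks:
        p = tta_predict(net, image, cfg)
        out = p if out is None else out + p
    return (out / len(networks)).astype(np.float32)


def probabilities_to_labels(probs: np.ndarray) -> np.ndarray:
    """Per-voxel argmax; exact ties resolve to the lower class index
    (background-favoring)."""
    return np.argmax(probs, axis=0).astype(np.int16)


def restore_to_original_grid(labels: Volume, crop: CropRecord,
                             original_spacing) -> Volume:
    """Map a predicted label map back to the original image grid: resample
    to the original spacing (nearest-neighbor), paste into the pre-crop
    grid at the crop offsets, background elsewhere."""
    from .preprocessing import resample

    restored = resample(labels, original_spacing, "label")
    extent = tuple(hi - lo for lo, hi in zip(crop.lower, crop.upper))
    data = restored.data
    # rounding in the resample shape formula can leave an off-by-one
    fixed = np.zeros(extent, dtype=data.dtype)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(extent, data.shape))
    fixed[sl] = data[sl]
    full = crop.paste_back(fixed)
    return Volume(full, spacing_mm=tuple(original_spacing))
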