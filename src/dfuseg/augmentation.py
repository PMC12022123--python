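"""Train-time augmentation: MixUp, Bézier intensity transforms, and
standard spatial/intensity patch augmentation.

MixUp forms convex combinations of pairs of patches and their one-hot
labels,

    x~ = lam * x_i + (1 - lam) * x_j
    y~ = lam * y_i + (1 - lam) * y_j,

with the mixing coefficient lam drawn from Beta(alpha, alpha).  Patch-based
sampling of sparse tumor volumes produces many all-background patches;
mixing them with foreground-bearing partners gives every training example a
soft foreground signal.

The Bézier intensity transform remaps min-max-scaled intensities through a
monotone cubic Bézier curve (optionally contrast-inverted), a domain
generalization device for training across modalities with different
intensity profiles (e.g. CT priors for an MRI task).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixUpSample",
    "BezierTransform",
    "AugmentParams",
    "mixup",
    "sample_lambda",
    "random_bezier",
    "bezier_intensity_transform",
    "augment_patch",
]


@dataclass
class MixUpSample:
    x_mix: np.ndarray
    y_mix: np.ndarray
    lam: float
    parent_ids: tuple = ("", "")


def mixup(xi: np.ndarray, yi: np.ndarray, xj: np.ndarray, yj: np.ndarray,
          lam: float, parent_ids: tuple = ("i", "j")) -> MixUpSample:
    """Convex combination of two patches and their per-class labels."""
    xi, xj = np.asarray(xi, np.float32), np.asarray(xj, np.float32)
    yi, yj = np.asarray(yi, np.float32), np.asarray(yj, np.float32)
    if xi.shape != xj.shape:
        raise ValueError(f"image shape mismatch {xi.shape} vs {xj.shape}")
    if yi.shape != yj.shape:
        raise ValueError(f"label shape mismatch {yi.shape} vs {yj.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    lam = float(lam)
    return MixUpSample(
        x_mix=lam * xi + (1.0 - lam) * xj,
        y_mix=lam * yi + (1.0 - lam) * yj,
        lam=lam,
        parent_ids=parent_ids,
    )


def sample_lambda(alpha: float, rng: np.random.Generator) -> float:
    """Draw the MixUp coefficient from Beta(alpha, alpha)."""
    if alpha <= 0:
        raise ValueError("Beta shape alpha must be positive")
    return float(rng.beta(alpha, alpha))


@dataclass
class BezierTransform:
    """Cubic Bézier intensity curve on the unit square.

    ``control_points`` are four (input, output) pairs; the first and last
    are pinned to (0,0) and (1,1).  With ``invert`` the output is mirrored
    (endpoints effectively (0,1) and (1,0)), reversing contrast.
    """

    control_points: tuple = ((0.0, 0.0), (0.25, 0.25), (0.75, 0.75), (1.0, 1.0))
    invert: bool = False

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=np.float64)
        if cp.shape != (4, 2):
            raise ValueError("need four (input, output) control points")
        if not (np.allclose(cp[0], (0, 0)) and np.allclose(cp[3], (1, 1))):
            raise ValueError("curve endpoints must be (0,0) and (1,1)")
        if cp[:, 0].min() < 0 or cp[:, 0].max() > 1:
            raise ValueError("control abscissae must lie in [0, 1]")

    def mapping(self, n: int = 1024) -> tuple[np.ndarray, np.ndarray]:
        """Sample the curve and resolve a monotone input->output mapping."""
        cp = np.asarray(self.control_points, dtype=np.float64)
        t = np.linspace(0.0, 1.0, n)[:, None]
        b = ((1 - t) ** 3 * cp[0] + 3 * (1 - t) ** 2 * t * cp[1]
             + 3 * (1 - t) * t ** 2 * cp[2] + t ** 3 * cp[3])
        xs = np.maximum.accumulate(b[:, 0])  # monotone branch
        ys = b[:, 1]
        if self.invert:
            ys = 1.0 - ys
        return xs, ys


def random_bezier(rng: np.random.Generator, invert_prob: float = 0.5
                  ) -> BezierTransform:
    """Endpoints fixed on the diagonal, two interior control points uniform
    on the unit square, contrast inversion with the given probability."""
    p1 = tuple(rng.uniform(0, 1, 2))
    p2 = tuple(rng.uniform(0, 1, 2))
    invert = bool(rng.uniform() < invert_prob)
    return BezierTransform(((0.0, 0.0), p1, p2, (1.0, 1.0)), invert=invert)


def bezier_intensity_transform(data: np.ndarray, t: BezierTransform
                               ) -> np.ndarray:
    """Min-max scale to [0,1], map through the curve, rescale back.

    A constant input cannot be rescaled and is returned unchanged.
    """
    data = np.asarray(data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        import warnings
        warnings.warn("constant input left unchanged by Bézier transform")
        return data.copy()
    unit = (data - lo) / (hi - lo)
    xs, ys = t.mapping()
    mapped = np.interp(unit, xs, ys)
    return (mapped * (hi - lo) + lo).astype(np.float32)


@dataclass
class AugmentParams:
    """Probabilities for the standard patch augmentations."""

    flip_prob: float = 0.5            # per axis
    noise_prob: float = 0.15
    noise_sd: float = 0.1
    scale_prob: float = 0.15
    scale_range: tuple[float, float] = (0.85, 1.15)


def augment_patch(patch: np.ndarray, labels: np.ndarray,
                  rng: np.random.Generator,
                  params: AugmentParams | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Random axis flips (spatial, applied to labels too), additive Gaussian
    noise and multiplicative intensity scaling (image only).

    ``patch`` is (C, D, H, W); ``labels`` is (D, H, W).
    """
    params = params or AugmentParams()
    patch = np.asarray(patch, np.float32).copy()
    labels = np.asarray(labels).copy()
    if patch.shape[1:] != labels.shape:
        raise ValueError("patch and labels spatial shapes differ")
    for ax in range(3):
        if rng.uniform() < params.flip_prob:
            patch = np.flip(patch, axis=ax + 1)
            labels = np.flip(labels, axis=ax)
    if rng.uniform() < params.noise_prob:
        patch = patch + rng.normal(0, params.noise_sd, patch.shape).astype(np.float32)
    if rng.uniform() < params.scale_prob:
        patch = patch * np.float32(rng.uniform(*params.scale_range))
    return np.ascontiguousarray(patch), np.ascontiguousarray(labels)
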