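"""Synthetic paired pre-/mid-treatment phantom cohorts.

Each case is an ellipsoidal "body" at a tissue intensity level surrounded
by air, carrying ellipsoidal lesions: up to one primary tumor (GTVp,
label 1, large and bright) and a few nodal targets (GTVn, label 2, smaller
and at roughly half the contrast), so the two foreground classes differ in
appearance the way a tumor and a lymph node do on T2w images.  The mid-treatment
volume reuses the same body but each lesion is shrunk by a random factor
and its centroid shifted by a bounded random displacement, emulating tumor
response between the two registered time points.  Intensities are loosely
T2w-like (lesions brighter than tissue) and the voxel grid is anisotropic
(default 1.2 x 0.5 x 0.5 mm).

Masks are derived from the analytic ellipsoid geometry before any edge
smoothing, so the label boundaries are crisp while image edges are soft.
Everything is deterministic given (seed, case_id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume, write_volume

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "PlacementError",
    "generate_case",
    "generate_cohort",
]


class PlacementError(RuntimeError):
    """A lesion could not be placed inside the body after bounded retries."""


@dataclass
class PhantomConfig:
    volume_shape: tuple[int, int, int] = (40, 96, 96)       # (z, y, x) voxels
    spacing_mm: tuple[float, float, float] = (1.2, 0.5, 0.5)
    n_gtvp: int = 1
    n_gtvn: int = 1
    lesion_radius_range_mm: tuple[float, float] = (4.0, 8.0)
    lesion_contrast: float = 120.0
    node_radius_range_mm: tuple[float, float] = (3.0, 6.0)
    node_contrast: float = 60.0
    mid_shrink_factor_range: tuple[float, float] = (0.6, 0.9)
    mid_shift_mm: float = 2.0
    noise_sd: float = 8.0
    background_level: float = 150.0
    air_level: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        for rng_mm in (self.lesion_radius_range_mm, self.node_radius_range_mm):
            lo, hi = rng_mm
            if lo <= 0 or hi < lo:
                raise ValueError("lesion radii must be positive and ordered")
        lo, hi = self.mid_shrink_factor_range
        if not (0 < lo <= hi <= 1.0):
            raise ValueError("mid_shrink_factor_range must lie in (0, 1]")
        if self.background_level <= self.air_level:
            raise ValueError("background_level must exceed air_level")
        if self.n_gtvp not in (0, 1):
            raise ValueError("n_gtvp must be 0 or 1")
        if not 0 <= self.n_gtvn <= 3:
            raise ValueError("n_gtvn must be in 0..3")


@dataclass
class PhantomCase:
    case_id: str
    pre_volume: Volume
    pre_mask: Volume
    mid_volume: Volume
    mid_mask: Volume


@dataclass
class _Lesion:
    center_mm: np.ndarray   # (z, y, x) physical coordinates
    semi_mm: np.ndarray     # per-axis semi-axes
    label: int


def _case_rng(seed: int, case_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(case_id.encode())])


def _coords_mm(shape, spacing) -> list[np.ndarray]:
    return [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]


def _ellipsoid_mask(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    zz, yy, xx = _coords_mm(shape, spacing)
    d = ((zz[:, None, None] - center_mm[0]) / semi_mm[0]) ** 2 \
        + ((yy[None, :, None] - center_mm[1]) / semi_mm[1]) ** 2 \
        + ((xx[None, None, :] - center_mm[2]) / semi_mm[2]) ** 2
    return d <= 1.0


def _body_geometry(config: PhantomConfig):
    extent = np.array(config.volume_shape) * np.array(config.spacing_mm)
    center = extent / 2.0
    semi = extent * 0.42
    return center, semi


def _place_lesions(config: PhantomConfig, rng: np.random.Generator,
                   case_id: str) -> list[_Lesion]:
    center, body_semi = _body_geometry(config)
    lesions: list[_Lesion] = []
    wanted = [(1, config.n_gtvp, config.lesion_radius_range_mm),
              (2, config.n_gtvn, config.node_radius_range_mm)]
    for label, count, radius_range in wanted:
        for _ in range(count):
            for _attempt in range(200):
                semi = rng.uniform(*radius_range, size=3)
                u = rng.uniform(-0.55, 0.55, size=3)
                cand = center + u * body_semi
                # fits inside the body?
                margin = np.sum(((cand - center) / (body_semi - semi)) ** 2)
                if np.any(body_semi - semi <= 0) or margin > 1.0:
                    continue
                # avoid overlap with already-placed lesions
                ok = all(
                    np.linalg.norm(cand - l.center_mm)
                    > 1.25 * (semi.max() + l.semi_mm.max())
                    for l in lesions
                )
                if ok:
                    lesions.append(_Lesion(cand, semi, label))
                    break
            else:
                raise PlacementError(
                    f"could not place a label-{label} lesion in case '{case_id}'")
    return lesions


def _render(config: PhantomConfig, lesions: list[_Lesion],
            rng: np.random.Generator) -> tuple[Volume, Volume]:
    shape, spacing = config.volume_shape, config.spacing_mm
    center, body_semi = _body_geometry(config)
    body = _ellipsoid_mask(shape, spacing, center, body_semi)
    mask = np.zeros(shape, dtype=np.int16)
    contrast = {1: config.lesion_contrast, 2: config.node_contrast}
    lesion_field = np.zeros(shape, dtype=np.float32)
    for l in lesions:
        m = _ellipsoid_mask(shape, spacing, l.center_mm, l.semi_mm)
        mask[m] = l.label
        lesion_field[m] = contrast[l.label]
    body_soft = ndimage.gaussian_filter(body.astype(np.float32), sigma=1.0)
    lesion_soft = ndimage.gaussian_filter(lesion_field, sigma=1.0)
    image = (config.air_level
             + (config.background_level - config.air_level) * body_soft
             + lesion_soft)
    image = image + rng.normal(0.0, config.noise_sd, shape)
    vol = Volume(image.astype(np.float32), spacing_mm=spacing)
    return vol, Volume(mask, spacing_mm=spacing)


def generate_case(config: PhantomConfig, case_id: str) -> PhantomCase:
    """Build one paired pre/mid phantom case, deterministic in
    (config.seed, case_id)."""
    rng = _case_rng(config.seed, case_id)
    pre_lesions = _place_lesions(config, rng, case_id)

    mid_lesions = []
    for l in pre_lesions:
        factor = rng.uniform(*config.mid_shrink_factor_range)
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.zeros(3)
        shift = direction * rng.uniform(0.0, config.mid_shift_mm)
        # keep the shrunken lesion overlapping its parent
        max_shift = max(0.0, float(l.semi_mm.min()) * (1.0 + factor) * 0.45)
        if np.linalg.norm(shift) > max_shift:
            shift = shift * (max_shift / np.linalg.norm(shift))
        mid_lesions.append(_Lesion(l.center_mm + shift, l.semi_mm * factor,
                                   l.label))

    pre_vol, pre_mask = _render(config, pre_lesions, rng)
    mid_vol, mid_mask = _render(config, mid_lesions, rng)
    return PhantomCase(case_id, pre_vol, pre_mask, mid_vol, mid_mask)


CASE_FILES = ("pre_image.nii.gz", "pre_mask.nii.gz",
              "mid_image.nii.gz", "mid_mask.nii.gz")


def generate_cohort(config: PhantomConfig, n_cases: int,
                    out_dir: str | Path) -> list[str]:
    """Write ``n_cases`` phantom cases as NIfTI plus a cohort manifest CSV.

    Re-running with identical config reproduces byte-identical arrays.
    Returns the list of case ids.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    ids = []
    for i in range(n_cases):
        case_id = f"case_{i:03d}"
        case = generate_case(config, case_id)
        case_dir = out_dir / case_id
        paths = {}
        for fname, vol in zip(CASE_FILES, (case.pre_volume, case.pre_mask,
                                           case.mid_volume, case.mid_mask)):
            paths[fname.split(".")[0]] = str(write_volume(vol, case_dir / fname))
        rows.append({"case_id": case_id, **paths})
        ids.append(case_id)
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)
    return ids
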