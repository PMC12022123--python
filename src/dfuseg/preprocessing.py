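"""Cross-modality preprocessing: body masking, cropping, normalization,
resampling and histogram matching.

Two pipeline orders are provided, mirroring the two dataset styles the
segmentation framework targets:

* MRI style: body mask (threshold + largest component + morphology) ->
  crop to the head region along x and y -> Z-score -> resample to
  1.2 x 0.5 x 0.5 mm;
* CT-for-pretraining style: the same mask/crop, then histogram matching to
  an MRI reference before Z-score and resampling, harmonizing CT intensity
  statistics with the downstream MRI task.

Histogram matching is a monotone quantile mapping (256 levels by default):
it never reorders voxel intensities and brings the source's empirical CDF
toward the reference's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import Volume

__all__ = [
    "CropRecord",
    "EmptyBodyError",
    "compute_body_mask",
    "crop_to_body",
    "zscore_normalize",
    "resample",
    "histogram_match",
    "preprocess_case",
    "PreprocessedCase",
]

DEFAULT_BODY_THRESHOLD = 60.0
DEFAULT_TARGET_SPACING = (1.2, 0.5, 0.5)


class EmptyBodyError(ValueError):
    """No voxel exceeded the body threshold."""


@dataclass
class CropRecord:
    """Half-open 0-based index bounds of a crop in the pre-crop grid."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    original_shape: tuple[int, int, int]

    def __post_init__(self):
        for lo, hi, n in zip(self.lower, self.upper, self.original_shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(
                    f"invalid crop bounds {self.lower}..{self.upper} "
                    f"for shape {self.original_shape}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))

    def paste_back(self, data: np.ndarray, fill=0) -> np.ndarray:
        """Place cropped-grid data back into a full-size array."""
        expected = tuple(hi - lo for lo, hi in zip(self.lower, self.upper))
        if data.shape != expected:
            raise ValueError(
                f"data shape {data.shape} does not match crop extent {expected}")
        out = np.full(self.original_shape, fill, dtype=data.dtype)
        out[self.slices] = data
        return out


def compute_body_mask(vol: Volume, threshold: float = DEFAULT_BODY_THRESHOLD
                      ) -> Volume:
    """Threshold, keep the largest connected component, close and fill.

    Closing uses a disk of radius 2 in-plane (the z axis is left alone —
    the through-plane spacing is much coarser), followed by 3D hole
    filling, then the largest component is re-selected so the result is a
    single connected body.
    """
    data = np.asarray(vol.data)
    if not np.all(np.isfinite(data)):
        raise ValueError("body masking requires finite intensities")
    fg = data > threshold
    if not fg.any():
        raise EmptyBodyError(
            f"no voxel above body threshold {threshold}")
    labeled, n = ndimage.label(fg)
    largest = np.argmax(ndimage.sum_labels(fg, labeled, range(1, n + 1))) + 1
    body = labeled == largest
    disk = np.zeros((1, 5, 5), dtype=bool)
    yy, xx = np.mgrid[-2:3, -2:3]
    disk[0] = yy**2 + xx**2 <= 4
    body = ndimage.binary_closing(body, structure=disk)
    body = ndimage.binary_fill_holes(body)
    labeled, n = ndimage.label(body)
    if n > 1:
        largest = np.argmax(
            ndimage.sum_labels(body, labeled, range(1, n + 1))) + 1
        body = labeled == largest
    return vol.with_data(body.astype(np.uint8))


def crop_to_body(vol: Volume, body: Volume,
                 axes: tuple[int, ...] = (1, 2)) -> tuple[Volume, CropRecord]:
    """Crop to the tight bounding box of the body along the given axes
    (defaults to y and x; z untouched)."""
    mask = np.asarray(body.data).astype(bool)
    if not mask.any():
        raise ValueError("cannot crop to an empty body mask")
    lower, upper = [], []
    for ax in range(3):
        if ax in axes:
            proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
            idx = np.flatnonzero(proj)
            lower.append(int(idx[0]))
            upper.append(int(idx[-1]) + 1)
        else:
            lower.append(0)
            upper.append(mask.shape[ax])
    rec = CropRecord(tuple(lower), tuple(upper), mask.shape)
    return vol.with_data(vol.data[rec.slices].copy()), rec


def zscore_normalize(vol: Volume, mask: Volume | None = None) -> Volume:
    """Z-score standardization over the whole volume, or within a mask."""
    data = np.asarray(vol.data, dtype=np.float64)
    region = data[np.asarray(mask.data).astype(bool)] if mask is not None else data
    sd = region.std()
    if sd == 0:
        raise ValueError("zero variance: cannot Z-score normalize")
    out = (data - region.mean()) / sd
    return vol.with_data(out.astype(np.float32))


def resample(vol: Volume, target_spacing_mm, interpolation: str = "image"
             ) -> Volume:
    """Resample to a target spacing.

    Output shape is round(shape * spacing / target) per axis. ``image``
    uses cubic B-spline interpolation, ``label`` nearest-neighbor (which
    preserves the label value set).
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be positive")
    if interpolation not in ("image", "label"):
        raise ValueError("interpolation must be 'image' or 'label'")
    in_shape = np.array(vol.shape)
    in_spacing = np.array(vol.spacing_mm)
    out_shape = np.rint(in_shape * in_spacing / np.array(target)).astype(int)
    out_shape = np.maximum(out_shape, 1)

    is_label = interpolation == "label"
    src = vol.with_data(
        vol.data.astype(np.int16 if is_label else np.float32)).to_sitk()
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(target[::-1]))
    res.SetSize([int(s) for s in out_shape[::-1]])
    res.SetOutputOrigin(src.GetOrigin())
    res.SetOutputDirection(src.GetDirection())
    res.SetInterpolator(
        sitk.sitkNearestNeighbor if is_label else sitk.sitkBSpline)
    res.SetDefaultPixelValue(0)
    out = Volume.from_sitk(res.Execute(src))
    if is_label:
        out.data = out.data.astype(np.int16)
    return out


def histogram_match(source: Volume, reference: Volume,
                    n_levels: int = 256) -> Volume:
    """Monotone quantile mapping of source intensities onto the reference
    distribution."""
    src = np.asarray(source.data, dtype=np.float64)
    ref = np.asarray(reference.data, dtype=np.float64)
    if src.max() == src.min():
        raise ValueError("constant source volume cannot be histogram matched")
    q = np.linspace(0.0, 1.0, n_levels)
    src_q = np.quantile(src, q)
    ref_q = np.quantile(ref, q)
    matched = np.interp(src, src_q, ref_q)
    return source.with_data(matched.astype(np.float32))


@dataclass
class PreprocessedCase:
    """Outputs of the full pipeline plus what is needed to map predictions
    back to the original grid."""

    image: Volume
    labels: Volume | None
    extra_images: list[Volume]
    crop: CropRecord
    original_spacing: tuple[float, float, float]
    original_shape: tuple[int, int, int]


def preprocess_case(image: Volume,
                    labels: Volume | None = None,
                    extra_images: tuple[Volume, ...] = (),
                    extra_labels: tuple[Volume, ...] = (),
                    body_threshold: float = DEFAULT_BODY_THRESHOLD,
                    target_spacing=DEFAULT_TARGET_SPACING,
                    match_reference: Volume | None = None,
                    zscore_in_mask: bool = False) -> PreprocessedCase:
    """Run the full pipeline on one case.

    Order: body mask -> crop (y, x) -> [histogram match] -> Z-score ->
    resample.  ``extra_images`` (e.g. a registered prior scan) share the
    primary image's body crop and are Z-scored individually;
    ``extra_labels`` (e.g. the prior's label map) follow with
    nearest-neighbor resampling.  The returned record inverts the geometry
    changes exactly.
    """
    body = compute_body_mask(image, body_threshold)
    cropped, rec = crop_to_body(image, body)
    body_cropped = body.with_data(body.data[rec.slices].copy())

    def _norm(v: Volume) -> Volume:
        if match_reference is not None:
            v = histogram_match(v, match_reference)
        return zscore_normalize(v, body_cropped if zscore_in_mask else None)

    out_img = resample(_norm(cropped), target_spacing, "image")
    out_labels = None
    if labels is not None:
        lab_c = labels.with_data(labels.data[rec.slices].copy())
        out_labels = resample(lab_c, target_spacing, "label")
    extras = []
    for v in extra_images:
        vc = v.with_data(v.data[rec.slices].copy())
        extras.append(resample(_norm(vc), target_spacing, "image"))
    for v in extra_labels:
        vc = v.with_data(v.data[rec.slices].copy())
        extras.append(resample(vc, target_spacing, "label"))
    return PreprocessedCase(
        image=out_img,
        labels=out_labels,
        extra_images=extras,
        crop=rec,
        original_spacing=image.spacing_mm,
        original_shape=image.shape,
    )
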