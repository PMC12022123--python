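"""The in-memory 3D image container and NIfTI I/O.

Arrays are always ordered (z, y, x) with per-axis voxel spacing in mm in
the same order; SimpleITK's (x, y, z) convention is converted at the I/O
boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "read_volume", "write_volume"]

_IDENTITY_DIR = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


@dataclass
class Volume:
    """A 3D scalar image with geometry metadata.

    ``data`` is (z, y, x); ``spacing_mm`` and ``origin`` follow the same
    axis order.  ``direction`` is the SimpleITK row-major 3x3 cosine matrix
    (kept verbatim; the package assumes axis-aligned volumes).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIR

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D (z, y, x)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))

    def is_label_map(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer)

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data)
        img.SetSpacing(tuple(self.spacing_mm[::-1]))  # (x, y, z)
        img.SetOrigin(tuple(self.origin[::-1]))
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        return cls(
            data=sitk.GetArrayFromImage(img),
            spacing_mm=tuple(img.GetSpacing()[::-1]),
            origin=tuple(img.GetOrigin()[::-1]),
            direction=tuple(img.GetDirection()),
        )


def read_volume(path: str | Path, as_labels: bool = False) -> Volume:
    vol = Volume.from_sitk(sitk.ReadImage(str(path)))
    if as_labels:
        vol.data = np.rint(vol.data).astype(np.int16)
    return vol


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if vol.is_label_map():
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    img = vol.with_data(data).to_sitk()
    sitk.WriteImage(img, str(path), useCompression=True)
    return path
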