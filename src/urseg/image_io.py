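"""Loading and saving of grayscale radiographs.

Accepts 8- and 16-bit unsigned grayscale PNG/TIFF; intensities are scaled to
[0, 1] by the maximum representable value of the input dtype.  A DICOM reader
(single-frame monochrome) is available behind the same contract when
``pydicom`` is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DegenerateInputError

MIN_SIDE = 32

__all__ = ["Radiograph", "load_radiograph", "load_dicom", "save_png", "to_radiograph"]


@dataclass(frozen=True)
class Radiograph:
    """A 2-D grayscale intensity raster in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise DegenerateInputError(f"expected a 2-D grayscale image, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise DegenerateInputError(
                f"image {px.shape} smaller than {MIN_SIDE}x{MIN_SIDE}"
            )
        if not np.all(np.isfinite(px)):
            raise DegenerateInputError("image contains non-finite intensities")
        if px.min() < 0 or px.max() > 1:
            raise DegenerateInputError("intensities must lie in [0, 1] after loading")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def m(self) -> int:
        """Height (row count)."""
        return self.pixels.shape[0]

    @property
    def n(self) -> int:
        """Width (column count)."""
        return self.pixels.shape[1]


def _scale_to_unit(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):  # tolerate gray stored as RGB
            arr = arr[..., :3].mean(axis=2)
        else:
            raise DegenerateInputError(f"multi-frame/color input of shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return arr


def load_radiograph(path: str | Path) -> Radiograph:
    """Read a PNG/TIFF grayscale image and normalize it to [0, 1]."""
    return Radiograph(_scale_to_unit(iio.imread(Path(path))))


def load_dicom(path: str | Path) -> Radiograph:
    """Read a single-frame monochrome DICOM image (requires ``pydicom``)."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM support requires the optional 'pydicom' package"
        ) from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise DegenerateInputError("only single-frame monochrome DICOM is supported")
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = 1.0 - arr
    return Radiograph(arr)


def to_radiograph(pixels: np.ndarray) -> Radiograph:
    """Wrap a float array already in [0, 1]."""
    return Radiograph(np.asarray(pixels, dtype=np.float64))


def save_png(path: str | Path, pixels: np.ndarray, bitdepth: int = 16) -> None:
    """Write a [0, 1] float raster (or a boolean mask) as PNG."""
    pixels = np.asarray(pixels)
    if pixels.dtype == bool:
        iio.imwrite(Path(path), (pixels.astype(np.uint8) * 255))
        return
    px = np.clip(pixels, 0.0, 1.0)
    if bitdepth == 8:
        iio.imwrite(Path(path), (px * 255).round().astype(np.uint8))
    else:
        iio.imwrite(Path(path), (px * 65535).round().astype(np.uint16))
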