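"""Standardization of raw forearm radiographs.

The pipeline crops the collimated/invalid border regions, downsamples,
rotates the forearm to run left-to-right (wrist at the right), extracts and
cleans the forearm mask (background set to exactly 0), then denoises with a
bilateral filter and equalizes the histogram over the mask.

All geometry is recorded in a :class:`~urseg.transform.StandardizationTransform`
so results can be mapped back to original-image coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import disk
from skimage.restoration import denoise_bilateral

from .errors import DegenerateInputError, StageError
from .image_io import MIN_SIDE, Radiograph, save_png, to_radiograph
from .transform import StandardizationTransform

__all__ = [
    "PreprocessConfig",
    "PreprocessedImage",
    "crop_valid_region",
    "correct_direction",
    "extract_and_clean",
    "denoise_enhance",
    "downsample",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    downsample_ratio: float = 0.7
    low_threshold: float = 0.2
    high_threshold: float = 0.6
    mask_threshold: float | None = None  # None -> Otsu
    dilation_radius: int = 5
    bilateral_sigma_spatial: float = 3.0
    bilateral_sigma_range: float = 0.1
    crop_profile_fraction: float = 0.05
    auto_invert: bool = True

    def __post_init__(self):
        if not (0.0 < self.downsample_ratio <= 1.0):
            raise ValueError(f"downsample_ratio must be in (0, 1], got {self.downsample_ratio}")
        if not (self.low_threshold < self.high_threshold):
            raise ValueError("low_threshold must be < high_threshold")


@dataclass
class PreprocessedImage:
    """A standardized raster, its forearm mask and the geometry record."""

    pixels: np.ndarray
    forearm_mask: np.ndarray
    transform: StandardizationTransform
    provenance: dict = field(default_factory=dict)
    tissue_mask: np.ndarray | None = None  # pre-dilation largest component
    smoothed_pixels: np.ndarray | None = None  # bilateral output, pre-equalization

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_png(directory / "standardized.png", self.pixels)
        save_png(directory / "forearm_mask.png", self.forearm_mask.astype(bool))
        record = dict(self.transform.to_json_dict())
        record["provenance"] = self.provenance
        (directory / "transform.json").write_text(json.dumps(record, indent=2))


FLATNESS_FRACTION = 0.25  # below this relative dynamic range: nothing to crop


def _valid_interval(profile: np.ndarray, fraction: float) -> tuple[int, int]:
    """Longest run of the profile above ``fraction`` of its dynamic range.

    A nearly flat profile (dynamic range under 25% of its maximum) has no
    low-content margins and yields the full interval.
    """
    lo, hi = float(profile.min()), float(profile.max())
    if hi <= lo or (hi - lo) < FLATNESS_FRACTION * hi:
        return 0, profile.size
    above = (profile - lo) > fraction * (hi - lo)
    if not above.any():
        return 0, profile.size
    # longest contiguous True run
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    best = np.argmax(stops - starts)
    return int(starts[best]), int(stops[best])


def crop_valid_region(
    image: Radiograph, config: PreprocessConfig
) -> tuple[Radiograph, tuple[int, int, int, int]]:
    """Crop to the valid coordinate ranges found on the intensity projections.

    Returns the sub-image and the crop box ``(r0, c0, r1, c1)`` in 0-based
    half-open original coordinates.
    """
    px = image.pixels
    row_profile = px.mean(axis=1)
    col_profile = px.mean(axis=0)
    r0, r1 = _valid_interval(row_profile, config.crop_profile_fraction)
    c0, c1 = _valid_interval(col_profile, config.crop_profile_fraction)
    if (r1 - r0) < MIN_SIDE or (c1 - c0) < MIN_SIDE:
        raise DegenerateInputError(
            f"valid region {(r0, c0, r1, c1)} smaller than {MIN_SIDE}x{MIN_SIDE}"
        )
    return to_radiograph(px[r0:r1, c0:c1]), (r0, c0, r1, c1)


def downsample(image: Radiograph, ratio: float) -> Radiograph:
    """Bilinear downsampling to ``round(ratio * dims)``."""
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if ratio == 1.0:
        return image
    m, n = image.shape
    out_m = max(int(round(ratio * m)), 1)
    out_n = max(int(round(ratio * n)), 1)
    sr, sc = out_m / m, out_n / n
    rows = (np.arange(out_m) + 0.5) / sr - 0.5
    cols = (np.arange(out_n) + 0.5) / sc - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndi.map_coordinates(image.pixels, grid, order=1, mode="nearest")
    return to_radiograph(np.clip(out, 0.0, 1.0))


def correct_direction(
    image: Radiograph, config: PreprocessConfig
) -> tuple[Radiograph, int]:
    """Rotate so the forearm runs left-to-right, wrist at the right.

    Portrait images are first rotated 90 degrees clockwise.  The horizontal
    sense is decided from the difference of the low- and high-threshold
    binary masks: if its mass concentrates in the left half the image is
    rotated a further 180 degrees.  Returns (image, rotation in degrees).
    """
    px = image.pixels
    rotation = 0
    if image.n < image.m:
        px = np.rot90(px, k=-1)
        rotation += 90
    mx = float(px.max())
    low = config.low_threshold * mx
    high = config.high_threshold * mx
    diff = (px > low) & (px <= high)
    count = int(diff.sum())
    if count == 0:
        raise DegenerateInputError(
            "direction thresholds are degenerate for this image (empty difference mask)"
        )
    # the hand is where the soft-minus-bone difference is greatest; if that
    # peak sits in the left half the forearm points right-to-left
    profile = diff.sum(axis=0).astype(float)
    kernel = np.ones(15) / 15.0
    profile = np.convolve(profile, kernel, mode="same")
    if int(np.argmax(profile)) < px.shape[1] // 2:
        px = np.rot90(px, k=2)
        rotation += 180
    return to_radiograph(np.ascontiguousarray(px)), rotation


def extract_and_clean(
    image: Radiograph, config: PreprocessConfig, return_core: bool = False
):
    """Forearm mask via global threshold + largest component + dilation.

    Intensities outside the (dilated) mask are set to exactly 0.  With
    ``return_core`` the pre-dilation component is returned as well.
    """
    px = image.pixels
    if config.mask_threshold is not None:
        thr = config.mask_threshold
    elif px.max() > px.min():
        # three-class split (background | soft tissue | bone): the lowest
        # threshold separates background from tissue robustly even when the
        # plain two-class Otsu valley falls between soft tissue and bone
        try:
            thr = float(threshold_multiotsu(px, classes=3)[0])
        except ValueError:
            thr = float(threshold_otsu(px))
    else:
        thr = px.min() - 1.0  # constant image: everything is foreground
    mask = px > thr
    if not mask.any():
        raise DegenerateInputError("empty forearm mask after global thresholding")
    labels, nlab = ndi.label(mask)
    if nlab > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    core = mask
    if config.dilation_radius > 0:
        mask = ndi.binary_dilation(mask, structure=disk(config.dilation_radius))
    cleaned = np.where(mask, px, 0.0)
    if return_core:
        return to_radiograph(cleaned), mask, core
    return to_radiograph(cleaned), mask


def _masked_equalize(px: np.ndarray, mask: np.ndarray, bins: int = 256) -> np.ndarray:
    vals = px[mask]
    hist, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist).astype(np.float64)
    cdf /= cdf[-1]
    out = np.interp(px, edges[1:], cdf, left=0.0)
    return np.where(mask, out, 0.0)


def denoise_enhance(
    image: Radiograph, config: PreprocessConfig, mask: np.ndarray | None = None,
    return_smoothed: bool = False,
):
    """Bilateral smoothing then histogram equalization over the mask pixels."""
    px = image.pixels
    if mask is None:
        mask = px > 0
    if not mask.any():
        raise DegenerateInputError("forearm mask is empty")
    smoothed = np.clip(
        denoise_bilateral(
            px,
            sigma_color=config.bilateral_sigma_range,
            sigma_spatial=config.bilateral_sigma_spatial,
        ),
        0.0,
        1.0,
    )
    out = to_radiograph(np.clip(_masked_equalize(smoothed, mask), 0.0, 1.0))
    if return_smoothed:
        return out, np.where(mask, smoothed, 0.0)
    return out


def preprocess(image: Radiograph, config: PreprocessConfig | None = None) -> PreprocessedImage:
    """Full standardization: crop, downsample, orient, clean, denoise/enhance.

    Downsampling happens right after the crop so the heavier stages run at
    the working resolution.
    """
    config = config or PreprocessConfig()
    provenance: dict = {}

    px = image.pixels
    inverted = False
    if config.auto_invert:
        b = max(2, min(px.shape) // 20)
        border = np.concatenate(
            [px[:b].ravel(), px[-b:].ravel(), px[:, :b].ravel(), px[:, -b:].ravel()]
        )
        center = px[px.shape[0] // 4 : -px.shape[0] // 4, px.shape[1] // 4 : -px.shape[1] // 4]
        if np.median(border) > np.median(center):
            px = 1.0 - px
            inverted = True
    provenance["inverted"] = inverted
    work = to_radiograph(px)

    try:
        work, crop_box = crop_valid_region(work, config)
    except Exception as exc:
        raise StageError("crop", exc) from exc
    provenance["crop_box"] = list(crop_box)

    try:
        pre_shape = work.shape
        work = downsample(work, config.downsample_ratio)
        scale = (work.shape[0] / pre_shape[0], work.shape[1] / pre_shape[1])
    except Exception as exc:
        raise StageError("downsample", exc) from exc
    provenance["ratio"] = config.downsample_ratio
    scaled_shape = work.shape

    try:
        work, rotation = correct_direction(work, config)
    except Exception as exc:
        raise StageError("direction", exc) from exc
    provenance["rotation_deg"] = rotation

    try:
        work, mask, core = extract_and_clean(work, config, return_core=True)
    except Exception as exc:
        raise StageError("clean", exc) from exc

    try:
        work, smoothed = denoise_enhance(work, config, mask, return_smoothed=True)
    except Exception as exc:
        raise StageError("enhance", exc) from exc

    transform = StandardizationTransform(
        crop_box=crop_box,
        scale=scale,
        rot_k_cw=(rotation // 90) % 4,
        scaled_shape=scaled_shape,
        inverted=inverted,
    )
    return PreprocessedImage(
        pixels=work.pixels, forearm_mask=mask, transform=transform,
        provenance=provenance, tissue_mask=core, smoothed_pixels=smoothed,
    )
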