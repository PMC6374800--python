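"""Cost-map construction for minimum-cost path tracing.

Two maps are built from the standardized image: the vertical map ``I1``
(low along horizontal edges, used for diaphysis tracing) and the horizontal
map ``I2`` (low along vertical edges, used for wrist-joint tracing).  Each is
a convex combination of a scaled inverted Sobel gradient magnitude and an
inverted binary Canny edge mask:

    I1 = lambda1 * f_Gy + (1 - lambda1) * f_c
    I2 = lambda2 * f_Gx + (1 - lambda2) * f_c

with f_G = 1 - |G| / max|G| and f_c = 0 on Canny edges, 1 elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny

from .image_io import save_png

logger = logging.getLogger(__name__)

__all__ = ["CostMapPair", "scaled_inverted_gradient", "canny_cost", "build_cost_maps"]

DEFAULT_LAMBDA1 = 0.3
DEFAULT_LAMBDA2 = 0.7
CANNY_SIGMA = 1.4
CANNY_HIGH_PERCENTILE = 90.0
CANNY_LOW_FACTOR = 0.4


@dataclass(frozen=True)
class CostMapPair:
    I1: np.ndarray
    I2: np.ndarray
    lambda1: float
    lambda2: float
    canny_mask: np.ndarray
    Gy: np.ndarray
    Gx: np.ndarray

    def save(self, directory) -> None:  # debugging aid
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_png(directory / "cost_vertical.png", self.I1)
        save_png(directory / "cost_horizontal.png", self.I2)


def _sobel(pixels: np.ndarray, axis: int) -> np.ndarray:
    # reflected-boundary Sobel, absolute response (both edge polarities cost equally)
    return np.abs(ndi.sobel(np.asarray(pixels, float), axis=axis, mode="reflect"))


def _frame_to_one(arr: np.ndarray) -> np.ndarray:
    arr[0, :] = arr[-1, :] = 1.0
    arr[:, 0] = arr[:, -1] = 1.0
    return arr


def scaled_inverted_gradient(pixels: np.ndarray, axis: int) -> np.ndarray:
    """``1 - |G|/max|G|`` for the Sobel gradient along ``axis`` (0=vertical).

    A constant image (max gradient 0) maps to an all-ones raster.  The
    outermost 1-px frame is set to 1 to keep paths off the image border.
    """
    g = _sobel(pixels, axis)
    gmax = g.max()
    if gmax == 0:
        logger.warning("constant image: gradient cost map defined as all ones")
        return np.ones_like(g)
    return _frame_to_one(1.0 - g / gmax)


def canny_cost(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverted Canny edge mask: 0 on edges, 1 elsewhere.

    Thresholds are derived from the smoothed gradient magnitude (high = 90th
    percentile of nonzero values, low = 0.4 * high).  Returns (cost, edge mask).
    """
    pixels = np.asarray(pixels, float)
    smoothed = ndi.gaussian_filter(pixels, CANNY_SIGMA)
    mag = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    nonzero = mag[mag > 0]
    if nonzero.size == 0:
        edges = np.zeros(pixels.shape, dtype=bool)
    else:
        high = float(np.percentile(nonzero, CANNY_HIGH_PERCENTILE))
        edges = canny(
            pixels, sigma=CANNY_SIGMA,
            low_threshold=CANNY_LOW_FACTOR * high, high_threshold=high,
        )
    edges[0, :] = edges[-1, :] = False
    edges[:, 0] = edges[:, -1] = False
    cost = np.where(edges, 0.0, 1.0)
    return cost, edges


def build_cost_maps(
    pixels: np.ndarray,
    lambda1: float = DEFAULT_LAMBDA1,
    lambda2: float = DEFAULT_LAMBDA2,
) -> CostMapPair:
    """Build the weighted vertical/horizontal cost maps in [0, 1]."""
    for name, lam in (("lambda1", lambda1), ("lambda2", lambda2)):
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {lam}")
    f_gy = scaled_inverted_gradient(pixels, axis=0)
    f_gx = scaled_inverted_gradient(pixels, axis=1)
    f_c, edges = canny_cost(pixels)
    i1 = lambda1 * f_gy + (1.0 - lambda1) * f_c
    i2 = lambda2 * f_gx + (1.0 - lambda2) * f_c
    return CostMapPair(
        I1=i1, I2=i2, lambda1=lambda1, lambda2=lambda2,
        canny_mask=edges, Gy=_sobel(pixels, 0), Gx=_sobel(pixels, 1),
    )
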