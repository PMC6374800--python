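"""Segmentation evaluation: overlap and boundary-distance metrics.

Overlap metrics (DSC, sensitivity, false-positive rate) are computed from
pixel confusion counts.  Boundary metrics (MAD, signed MSD) are computed
over rasterized 8-connected contour pixel sets; the sign of MSD is fixed so
that a positive value means the first (ground-truth) contour is on average
larger than the second.

The regional report splits the ground-truth longitudinal extent into three
equal column bands (proximal, middle, distal, left to right) and evaluates
every metric per band and for the whole image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import line as _sk_line

from .dptrace import rasterize_closed_polygon

__all__ = [
    "ConfusionCounts",
    "RegionMetrics",
    "EvalReport",
    "confusion",
    "dsc",
    "sens",
    "fpr",
    "contour_pixels",
    "mad",
    "msd",
    "regional_report",
]

REGIONS = ("whole", "proximal", "middle", "distal")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(gt_mask: np.ndarray, pred_mask: np.ndarray) -> ConfusionCounts:
    gt = np.asarray(gt_mask, dtype=bool)
    pred = np.asarray(pred_mask, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    return ConfusionCounts(
        TP=int((gt & pred).sum()),
        FP=int((~gt & pred).sum()),
        FN=int((gt & ~pred).sum()),
    )


def _require_gt(counts: ConfusionCounts):
    if counts.TP + counts.FN == 0:
        raise ValueError("metric undefined: ground truth has no foreground pixels")


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FN + FP)."""
    _require_gt(counts)
    return 2.0 * counts.TP / (2.0 * counts.TP + counts.FN + counts.FP)


def sens(counts: ConfusionCounts) -> float:
    """Sensitivity TP / (TP + FN)."""
    _require_gt(counts)
    return counts.TP / (counts.TP + counts.FN)


def fpr(counts: ConfusionCounts) -> float:
    """False-positive rate FP / (TP + FN)."""
    _require_gt(counts)
    return counts.FP / (counts.TP + counts.FN)


# ----------------------------------------------------------------------
# boundary distances
# ----------------------------------------------------------------------


def contour_pixels(contour: np.ndarray) -> np.ndarray:
    """Unique integer boundary pixels of a polygon, densified 8-connectedly.

    Accepts a polygon as an (L, 2) float/int vertex array.  Vertices already
    given as a dense pixel set pass through (after rounding and dedup).
    """
    poly = np.asarray(contour, dtype=float).reshape(-1, 2)
    if poly.shape[0] == 0:
        raise ValueError("empty contour")
    pts = []
    verts = np.round(poly).astype(int)
    for (r0, c0), (r1, c1) in zip(verts[:-1], verts[1:]):
        rr, cc = _sk_line(r0, c0, r1, c1)
        pts.append(np.stack([rr, cc], axis=1))
    pts.append(verts[-1:])
    out = np.unique(np.concatenate(pts, axis=0), axis=0)
    return out


def _as_pixel_set(contour) -> np.ndarray:
    arr = np.asarray(contour)
    if arr.size == 0:
        raise ValueError("empty contour")
    if np.issubdtype(arr.dtype, np.integer):
        return np.unique(arr.reshape(-1, 2), axis=0)
    return contour_pixels(arr)


def mad(contourA, contourB) -> float:
    """Symmetric mean absolute distance between two contour pixel sets."""
    a = _as_pixel_set(contourA).astype(float)
    b = _as_pixel_set(contourB).astype(float)
    da = cKDTree(b).query(a)[0]
    db = cKDTree(a).query(b)[0]
    return float((da.sum() + db.sum()) / (len(a) + len(b)))


def _require_closed(poly: np.ndarray):
    poly = np.asarray(poly, dtype=float).reshape(-1, 2)
    if poly.shape[0] < 4 or not np.allclose(poly[0], poly[-1]):
        raise ValueError("contour must be a closed polygon (first vertex == last)")
    return poly


def _signed_distances(points: np.ndarray, other_pixels: np.ndarray, other_inside: np.ndarray) -> np.ndarray:
    """D(p, S): +d inside the other contour, 0 on it, -d outside."""
    d = cKDTree(other_pixels.astype(float)).query(points.astype(float))[0]
    h, w = other_inside.shape
    r = np.clip(points[:, 0], 0, h - 1)
    c = np.clip(points[:, 1], 0, w - 1)
    inside = other_inside[r, c] & ~(
        (points[:, 0] < 0) | (points[:, 0] >= h) | (points[:, 1] < 0) | (points[:, 1] >= w)
    )
    sign = np.where(d == 0, 0.0, np.where(inside, 1.0, -1.0))
    return sign * d


def _polygon_regions(poly: np.ndarray):
    """(boundary pixel set, strict-interior raster) for a closed polygon."""
    pix = contour_pixels(poly)
    h = int(max(pix[:, 0].max(), 0)) + 2
    w = int(max(pix[:, 1].max(), 0)) + 2
    filled = rasterize_closed_polygon(np.asarray(poly, float), (h, w))
    boundary = np.zeros_like(filled)
    keep = (pix[:, 0] >= 0) & (pix[:, 1] >= 0)
    boundary[pix[keep, 0], pix[keep, 1]] = True
    interior = filled & ~boundary
    return pix, interior


def msd(contourA, contourB) -> float:
    """Signed mean distance; positive when contour A is on average larger.

    Both arguments must be closed polygons.  Antisymmetric:
    ``msd(A, B) == -msd(B, A)`` and ``msd(A, A) == 0``.
    """
    polyA = _require_closed(contourA)
    polyB = _require_closed(contourB)
    pixA, intA = _polygon_regions(polyA)
    pixB, intB = _polygon_regions(polyB)
    dA = _signed_distances(pixA, pixB, intB)  # A's pixels vs B
    dB = _signed_distances(pixB, pixA, intA)  # B's pixels vs A
    return float((dB.sum() - dA.sum()) / (len(pixA) + len(pixB)))


# ----------------------------------------------------------------------
# regional report
# ----------------------------------------------------------------------


@dataclass
class RegionMetrics:
    DSC: float
    Sens: float
    FPR: float
    MAD: float
    MSD: float


@dataclass
class EvalReport:
    regions: dict  # region name -> RegionMetrics | None

    def to_json_dict(self) -> dict:
        return {
            name: (asdict(m) if m is not None else None)
            for name, m in self.regions.items()
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


def _band_bounds(cmin: int, cmax: int) -> list[tuple[int, int]]:
    """Three near-equal column bands tiling [cmin, cmax] inclusive."""
    length = cmax - cmin + 1
    cuts = [cmin + round(k * length / 3) for k in range(4)]
    return [(cuts[k], cuts[k + 1] - 1) for k in range(3)]


def _pooled_pixels(contours) -> np.ndarray:
    return np.concatenate([_as_pixel_set(c) for c in contours], axis=0)


def _masks_inside(contours, shape) -> np.ndarray:
    inside = np.zeros(shape, dtype=bool)
    for c in contours:
        inside |= rasterize_closed_polygon(np.asarray(c, float), shape)
    return inside


def regional_report(
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    gt_contours,
    pred_contours,
) -> EvalReport:
    """All five metrics for the whole image and the three column bands.

    ``gt_contours`` / ``pred_contours`` are sequences of closed polygons
    (both bones pooled).  The band split uses the ground-truth column extent.
    """
    gt = np.asarray(gt_mask, dtype=bool)
    pred = np.asarray(pred_mask, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError("mask shape mismatch")
    if not gt.any():
        raise ValueError("ground-truth mask is empty")

    gt_pix = _pooled_pixels(gt_contours)
    pred_pix = _pooled_pixels(pred_contours)
    gt_inside = _masks_inside(gt_contours, gt.shape)
    pred_inside = _masks_inside(pred_contours, pred.shape)

    # distances of every boundary pixel to the full opposing boundary
    d_gt = _signed_distances(gt_pix, pred_pix, pred_inside)
    d_pred = _signed_distances(pred_pix, gt_pix, gt_inside)

    cols = np.flatnonzero(gt.any(axis=0))
    cmin, cmax = int(cols[0]), int(cols[-1])
    bands = {"whole": (0, gt.shape[1] - 1)}
    for name, bounds in zip(("proximal", "middle", "distal"), _band_bounds(cmin, cmax)):
        bands[name] = bounds

    regions: dict = {}
    for name, (lo, hi) in bands.items():
        gt_band = gt[:, lo : hi + 1]
        if not gt_band.any():
            regions[name] = None
            continue
        counts = confusion(gt_band, pred[:, lo : hi + 1])
        in_gt = (gt_pix[:, 1] >= lo) & (gt_pix[:, 1] <= hi)
        in_pred = (pred_pix[:, 1] >= lo) & (pred_pix[:, 1] <= hi)
        n_pts = int(in_gt.sum() + in_pred.sum())
        if n_pts == 0:
            regions[name] = None
            continue
        abs_sum = np.abs(d_gt[in_gt]).sum() + np.abs(d_pred[in_pred]).sum()
        signed_sum = d_pred[in_pred].sum() - d_gt[in_gt].sum()
        regions[name] = RegionMetrics(
            DSC=dsc(counts),
            Sens=sens(counts),
            FPR=fpr(counts),
            MAD=float(abs_sum / n_pts),
            MSD=float(signed_sum / n_pts),
        )
    return EvalReport(regions=regions)
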