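"""Seed-point detection on the standardized image.

The distal-end column ``x0`` is the deepest interior local minimum of the
forearm-mask vertical projection, searched left of the projection maximum.
The four diaphysis-edge seeds are the four most prominent peaks of the
vertical gradient-magnitude profile down a mid-diaphysis probe column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .errors import SeedDetectionError
from .preprocess import PreprocessedImage

__all__ = ["SeedSet", "locate_distal_end", "detect_seed_points"]

SMOOTH_WIDTH = 7  # moving-average width for the projection profile
MIN_PEAK_DISTANCE = 8  # minimum row separation between seed peaks
N_SEEDS = 4


@dataclass(frozen=True)
class SeedSet:
    """Distal-end column, projection peak, probe column and the 4 seeds.

    Seeds are (row, col) in standardized coordinates, sorted top to bottom:
    (bone1_upper, bone1_lower, bone2_upper, bone2_lower).
    """

    x0: int
    p_max: int
    probe_col: int
    seeds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.seeds) != N_SEEDS:
            raise SeedDetectionError(f"expected {N_SEEDS} seeds, got {len(self.seeds)}")
        rows = [s[0] for s in self.seeds]
        if sorted(rows) != rows or len(set(rows)) != N_SEEDS:
            raise SeedDetectionError(f"seed rows not strictly increasing: {rows}")

    def to_json_dict(self) -> dict:
        return {
            "x0": self.x0,
            "p_max": self.p_max,
            "probe_col": self.probe_col,
            "seeds": [list(s) for s in self.seeds],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


def _smooth(profile: np.ndarray, width: int = SMOOTH_WIDTH) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(profile.astype(float), kernel, mode="same")


def locate_distal_end(mask: np.ndarray) -> tuple[int, int]:
    """Find ``(x0, p_max)`` from the vertical projection of the forearm mask.

    ``p_max`` is the argmax of the (smoothed) per-column mask sums; ``x0`` is
    the deepest interior local minimum within columns ``[0, p_max]``.
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise SeedDetectionError("forearm mask is empty")
    projection = mask.sum(axis=0).astype(float)
    smoothed = _smooth(projection)
    p_max = int(np.argmax(smoothed))
    segment = smoothed[: p_max + 1]
    # interior local minima: both neighbors (within a small window) larger
    minima, _ = find_peaks(-segment, distance=5)
    minima = minima[(minima > 0) & (minima < p_max)]
    if minima.size == 0:
        raise SeedDetectionError(
            "no interior minimum in the vertical projection left of its maximum",
            profile=projection,
        )
    x0 = int(minima[np.argmin(segment[minima])])
    # sub-pixel refinement: parabola fitted to the smoothed projection around
    # the minimum (integer counts + smoothing alone bias the argmin)
    lo, hi = max(x0 - 5, 0), min(x0 + 6, p_max + 1)
    if hi - lo >= 5:
        xs = np.arange(lo, hi, dtype=float)
        coef = np.polyfit(xs, smoothed[lo:hi], 2)
        if coef[0] > 0:
            vertex = -coef[1] / (2 * coef[0])
            if lo <= vertex <= hi - 1:
                x0 = int(round(vertex))
    return x0, p_max


def _vertical_gradient_magnitude(pixels: np.ndarray) -> np.ndarray:
    # Sobel derivative along rows; /8 normalizes the stencil weights
    return np.abs(ndi.sobel(pixels, axis=0)) / 8.0


def _peaks_at_column(profile: np.ndarray) -> np.ndarray:
    """Rows of the 4 most prominent peaks (>=4 required), sorted by row."""
    peaks, props = find_peaks(profile, distance=MIN_PEAK_DISTANCE, prominence=0.0)
    if peaks.size < N_SEEDS:
        return peaks
    prom = props["prominences"]
    # top 4 by prominence; ties broken toward smaller row (stable mergesort
    # on -prominence keeps original row order within ties)
    order = np.argsort(-prom, kind="stable")[:N_SEEDS]
    return np.sort(peaks[order])


MAX_PAIR_FRACTION = 0.35  # bone thickness cap as a fraction of the tissue span
PAIR_MARGIN = 0.02  # bone interior must beat its flanks by this intensity margin


def _pair_ok(r1, r2, column, in_mask, span, bright) -> bool:
    sep = r2 - r1
    if not (MIN_PEAK_DISTANCE <= sep <= MAX_PAIR_FRACTION * span):
        return False
    q = max(sep // 4, 2)
    interior = np.median(column[r1 + q : r2 - q + 1])
    if interior < bright:  # bone interiors are the brightest tissue
        return False
    flank_w = max(sep // 2, 4)
    above = slice(max(r1 - flank_w, 0), r1)
    below = slice(r2 + 1, r2 + 1 + flank_w)
    for flank in (above, below):
        m = in_mask[flank]
        if m.size == 0 or m.mean() < 0.5:
            return False  # edge touches the tissue boundary: not a bone edge
        if np.median(column[flank][m]) + PAIR_MARGIN >= interior:
            return False
    return True


def _consistent_quadruple(
    profile: np.ndarray, column: np.ndarray, in_mask: np.ndarray, top_k: int = 10
) -> np.ndarray | None:
    """Best 4 peaks forming two bright-interior (bone) pairs inside the mask.

    Peaks are ranked by prominence; among the ``top_k`` candidates the
    quadruple (r1<r2<r3<r4) with maximal total prominence whose pairs
    (r1,r2) and (r3,r4) both look like bone cross-sections is returned.
    """
    from itertools import combinations

    peaks, props = find_peaks(profile, distance=MIN_PEAK_DISTANCE, prominence=0.0)
    if peaks.size < N_SEEDS:
        return None
    prom = props["prominences"]
    order = np.argsort(-prom, kind="stable")[:top_k]
    cand = peaks[order]
    cprom = prom[order]
    keep = in_mask[cand]
    cand, cprom = cand[keep], cprom[keep]
    if cand.size < N_SEEDS:
        return None
    span = int(in_mask.sum())
    bright = float(np.percentile(column[in_mask], 70))
    best, best_score = None, -np.inf
    for idx in combinations(range(cand.size), N_SEEDS):
        rows = np.sort(cand[list(idx)])
        score = cprom[list(idx)].sum()
        if score <= best_score:
            continue
        w1, w2 = rows[1] - rows[0], rows[3] - rows[2]
        if max(w1, w2) > 1.5 * min(w1, w2):
            continue  # the two bones have comparable thickness
        if _pair_ok(rows[0], rows[1], column, in_mask, span, bright) and _pair_ok(
            rows[2], rows[3], column, in_mask, span, bright
        ):
            best, best_score = rows, score
    return best


def detect_seed_points(image: PreprocessedImage, x0: int) -> SeedSet:
    """Detect the four diaphysis-edge seeds at the mid-diaphysis probe column.

    If fewer than four qualifying peaks are found at ``probe_col`` the probe
    is retried at +-10% and +-20% of ``x0`` before raising.
    """
    px = image.pixels
    mask = image.forearm_mask
    if not (0 <= x0 < px.shape[1]):
        raise SeedDetectionError(f"x0={x0} outside image width {px.shape[1]}")
    grad = _vertical_gradient_magnitude(px)
    base = int(round(x0 / 2))
    step = max(int(round(0.1 * x0)), 1)
    offsets = [0, step, -step, 2 * step, -2 * step]
    found: list[int] = []
    candidates: list[tuple[float, np.ndarray, int]] = []
    for off in offsets:
        probe_col = int(np.clip(base + off, 0, px.shape[1] - 1))
        # average over a few neighbouring columns: diaphysis edges are nearly
        # horizontal, so their peaks align while noise peaks cancel
        sl = slice(max(probe_col - 2, 0), probe_col + 3)
        profile = grad[:, sl].mean(axis=1)
        column = px[:, sl].mean(axis=1)
        quad = _consistent_quadruple(profile, column, mask[:, probe_col])
        if quad is not None:
            rows = quad
        else:
            rows = _peaks_at_column(profile)
            rows = rows[mask[rows, probe_col]] if rows.size else rows
        if rows.size >= N_SEEDS:
            rows, ratio = _snap_rows(np.asarray(rows[:N_SEEDS]), image, sl)
            if ratio >= MIN_EDGE_STRENGTH_RATIO and quad is not None:
                seeds = tuple((int(r), probe_col) for r in rows)
                return SeedSet(
                    x0=int(x0),
                    p_max=_projection_peak(mask),
                    probe_col=probe_col,
                    seeds=seeds,
                )
            candidates.append((ratio, rows, probe_col))
        found.extend(int(r) for r in rows)
        # equalization can wash out a weak edge: retry the quadruple search
        # on the pre-equalization (bilateral-only) gradient profile
        if image.smoothed_pixels is not None:
            smgrad = _vertical_gradient_magnitude(image.smoothed_pixels)
            smprofile = smgrad[:, sl].mean(axis=1)
            smcolumn = image.smoothed_pixels[:, sl].mean(axis=1)
            quad2 = _consistent_quadruple(smprofile, smcolumn, mask[:, probe_col])
            if quad2 is not None:
                rows2, ratio2 = _snap_rows(np.asarray(quad2), image, sl)
                if ratio2 >= MIN_EDGE_STRENGTH_RATIO:
                    return SeedSet(
                        x0=int(x0),
                        p_max=_projection_peak(mask),
                        probe_col=probe_col,
                        seeds=tuple((int(r), probe_col) for r in rows2),
                    )
                candidates.append((ratio2, rows2, probe_col))
    if candidates:
        # no probe column had four convincing edges; take the best available
        ratio, rows, probe_col = max(candidates, key=lambda c: c[0])
        return SeedSet(
            x0=int(x0),
            p_max=_projection_peak(mask),
            probe_col=probe_col,
            seeds=tuple((int(r), probe_col) for r in rows),
        )
    raise SeedDetectionError(
        f"fewer than {N_SEEDS} seed peaks found near probe column {base}",
        peaks=sorted(set(found)),
    )


SNAP_RADIUS = 6


MIN_EDGE_STRENGTH_RATIO = 0.2  # weakest seed edge vs strongest, pre-equalization


def _snap_rows(rows: np.ndarray, image: PreprocessedImage, sl: slice):
    """Snap seed rows to the nearest pre-equalization gradient peaks.

    Histogram equalization warps edge ramps (the steepest equalized point can
    sit a few pixels outside the true edge), so the final localization uses
    the bilateral-smoothed image whose edge response is symmetric.  Returns
    the snapped rows and the weakest/strongest edge-strength ratio, used to
    arbitrate between candidate probe columns.
    """
    if image.smoothed_pixels is None:
        return rows, 1.0
    prof = _vertical_gradient_magnitude(image.smoothed_pixels)[:, sl].mean(axis=1)
    snapped = rows.copy()
    strength = np.empty(rows.size)
    for i, r in enumerate(rows):
        lo = max(r - SNAP_RADIUS, 0)
        hi = min(r + SNAP_RADIUS + 1, prof.size)
        snapped[i] = lo + int(np.argmax(prof[lo:hi]))
        strength[i] = prof[snapped[i]]
    ratio = float(strength.min() / strength.max()) if strength.max() > 0 else 0.0
    # keep the original rows if snapping broke the strict ordering
    if np.any(np.diff(snapped) < MIN_PEAK_DISTANCE // 2):
        return rows, ratio
    return snapped, ratio


def _projection_peak(mask: np.ndarray) -> int:
    return int(np.argmax(_smooth(mask.sum(axis=0).astype(float))))
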