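"""Minimum-cost path tracing and contour assembly.

Paths are 3-connected: they advance exactly one slice per step along the
tracing axis (columns for diaphysis edges, rows for the wrist joint) while
moving at most one pixel on the other axis.  The cumulative minimum cost is
computed with the standard seam recurrence

    c(i, j) = I(i, j) + min(c(i-1, j-1), c(i, j-1), c(i+1, j-1))

with the out-of-range rows dropped at the top/bottom borders, then the
optimal path is recovered by backtracking from the minimum of the stop
slice (or from a fixed anchor point for the joint segment).

Ties are broken toward the row (or column) nearest the current one, then
toward the smaller index, so paths stay straight across flat cost regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as _sk_polygon, polygon_perimeter

from .costmaps import build_cost_maps
from .errors import ContourAssemblyError, SeedDetectionError, StageError, TracingError
from .image_io import Radiograph
from .preprocess import PreprocessConfig, preprocess
from .seeds import detect_seed_points, locate_distal_end
from .transform import StandardizationTransform

logger = logging.getLogger(__name__)

__all__ = [
    "TracedPath",
    "CumulativeCost",
    "URContours",
    "SegmentConfig",
    "cumulative_cost",
    "backtrack",
    "trace_diaphysis_edge",
    "trace_joint_segment",
    "assemble_contours",
    "rasterize_closed_polygon",
    "segment_image",
]

DEFAULT_WINDOW = 64
BAND_DIVISOR = 10


@dataclass(frozen=True)
class TracedPath:
    """An ordered 3-connected path through a cost map."""

    points: np.ndarray  # (L, 2) int (row, col)
    axis: int  # tracing axis: 1 = advance along columns, 0 = along rows
    total_cost: float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=int)
        object.__setattr__(self, "points", pts)
        steps = np.diff(pts, axis=0)
        along = steps[:, self.axis]
        across = steps[:, 1 - self.axis]
        if pts.shape[0] > 1 and (
            not np.all(np.abs(along) == 1)
            or np.unique(along).size > 1
            or np.any(np.abs(across) > 1)
        ):
            raise TracingError("path is not 3-connected along its tracing axis")

    def __len__(self) -> int:
        return self.points.shape[0]

    def cost_along(self, costmap: np.ndarray) -> float:
        return float(costmap[self.points[:, 0], self.points[:, 1]].sum())


@dataclass(frozen=True)
class CumulativeCost:
    """Cumulative minimum cost from a single seed point.

    ``c`` is in the cost map's own coordinates with ``inf`` marking slices
    not visited (before the seed, against the tracing direction).
    """

    c: np.ndarray
    costmap: np.ndarray
    seed: tuple[int, int]
    axis: int
    direction: int
    stop: int

    @property
    def N(self) -> int:
        """Slice length across the tracing axis."""
        return self.c.shape[1 - self.axis]


def _work_view(arr: np.ndarray, axis: int, direction: int) -> np.ndarray:
    """View with tracing along axis 1 in the +1 direction."""
    v = arr if axis == 1 else arr.T
    return v[:, ::-1] if direction == -1 else v


def _pt_to_work(pt, axis, direction, shape):
    r, c = int(pt[0]), int(pt[1])
    if axis == 0:
        r, c = c, r
    w = shape[1] if axis == 1 else shape[0]
    if direction == -1:
        c = w - 1 - c
    return r, c


def _pt_from_work(pt, axis, direction, shape):
    r, c = pt
    w = shape[1] if axis == 1 else shape[0]
    if direction == -1:
        c = w - 1 - c
    if axis == 0:
        r, c = c, r
    return int(r), int(c)


def cumulative_cost(
    costmap: np.ndarray,
    seed: tuple[int, int],
    axis: int = 1,
    direction: int = 1,
    stop: int | None = None,
) -> CumulativeCost:
    """Seam-DP cumulative minimum cost from ``seed`` to the ``stop`` slice."""
    M = np.asarray(costmap, dtype=float)
    if direction not in (-1, 1) or axis not in (0, 1):
        raise ValueError("axis must be 0/1 and direction +-1")
    sr, sc = int(seed[0]), int(seed[1])
    if not (0 <= sr < M.shape[0] and 0 <= sc < M.shape[1]):
        raise TracingError(f"seed {seed} outside cost map of shape {M.shape}")
    if stop is None:
        stop = (M.shape[axis] - 1) if direction == 1 else 0
    if not (0 <= stop < M.shape[axis]):
        raise TracingError(f"stop slice {stop} outside cost map of shape {M.shape}")

    W = _work_view(M, axis, direction)
    wr, wc = _pt_to_work((sr, sc), axis, direction, M.shape)
    wstop = _pt_to_work((0, stop) if axis == 1 else (stop, 0), axis, direction, M.shape)[1]
    if wstop < wc:
        raise TracingError("stop slice lies against the tracing direction")

    cw = np.full(W.shape, np.inf)
    cw[wr, wc] = W[wr, wc]
    inf = np.inf
    for j in range(wc + 1, wstop + 1):
        prev = cw[:, j - 1]
        up = np.concatenate(([inf], prev[:-1]))
        down = np.concatenate((prev[1:], [inf]))
        cw[:, j] = W[:, j] + np.minimum(prev, np.minimum(up, down))

    # map cumulative array back into the cost map's coordinates
    c = cw[:, ::-1] if direction == -1 else cw
    if axis == 0:
        c = c.T
    return CumulativeCost(
        c=np.ascontiguousarray(c), costmap=M, seed=(sr, sc), axis=axis,
        direction=direction, stop=int(stop),
    )


def _tie_argmin(values: np.ndarray, rows: np.ndarray, anchor: int) -> int:
    """Index of the minimum; ties go to the row nearest ``anchor``, then smaller."""
    best = values.min()
    cand = rows[values <= best]
    dist = np.abs(cand - anchor)
    cand = cand[dist == dist.min()]
    return int(cand.min())


def backtrack(cum: CumulativeCost, end: tuple[int, int] | None = None) -> TracedPath:
    """Recover the optimal path from the stop slice back to the seed."""
    M, axis, direction = cum.costmap, cum.axis, cum.direction
    W = _work_view(M, axis, direction)
    CW = _work_view(cum.c, axis, direction)
    wr0, wc0 = _pt_to_work(cum.seed, axis, direction, M.shape)
    wstop = _pt_to_work(
        (0, cum.stop) if axis == 1 else (cum.stop, 0), axis, direction, M.shape
    )[1]

    if end is None:
        col = CW[:, wstop]
        finite = np.flatnonzero(np.isfinite(col))
        if finite.size == 0:
            raise TracingError("stop slice unreachable from the seed")
        er = _tie_argmin(col[finite], finite, wr0)
    else:
        ew = _pt_to_work(end, axis, direction, M.shape)
        if ew[1] != wstop:
            raise TracingError(f"anchor {end} is not on the stop slice")
        er = ew[0]
        if not np.isfinite(CW[er, wstop]):
            raise TracingError(f"anchor {end} unreachable from seed {cum.seed}")

    total = float(CW[er, wstop])
    rows_work = [er]
    i = er
    for j in range(wstop, wc0, -1):
        lo, hi = max(i - 1, 0), min(i + 1, W.shape[0] - 1)
        cand = np.arange(lo, hi + 1)
        vals = CW[cand, j - 1]
        ok = np.isfinite(vals)
        i = _tie_argmin(vals[ok], cand[ok], i)
        rows_work.append(i)
    rows_work.reverse()

    pts = [
        _pt_from_work((r, wc0 + k), axis, direction, M.shape)
        for k, r in enumerate(rows_work)
    ]
    return TracedPath(points=np.array(pts, dtype=int), axis=axis, total_cost=total)


def trace_diaphysis_edge(
    I1: np.ndarray,
    seed: tuple[int, int],
    direction: int,
    window_w: int = DEFAULT_WINDOW,
    stop_col: int | None = None,
) -> TracedPath:
    """Chained windowed DP tracing along columns until ``stop_col``.

    Each window's end point re-seeds the next window, so the concatenated
    path spans the whole range between the seed column and ``stop_col``.
    """
    M = np.asarray(I1, dtype=float)
    if stop_col is None:
        stop_col = 0 if direction == -1 else M.shape[1] - 1
    if window_w < 1:
        raise ValueError("window_w must be >= 1")
    cur = (int(seed[0]), int(seed[1]))
    points = [cur]
    while cur[1] != stop_col:
        nxt = cur[1] + direction * window_w
        nxt = max(nxt, stop_col) if direction == -1 else min(nxt, stop_col)
        cum = cumulative_cost(M, cur, axis=1, direction=direction, stop=nxt)
        sub = backtrack(cum)
        points.extend(map(tuple, sub.points[1:]))
        cur = tuple(sub.points[-1])
    pts = np.array(points, dtype=int)
    total = float(M[pts[:, 0], pts[:, 1]].sum())
    return TracedPath(points=pts, axis=1, total_cost=total)


def trace_joint_segment(
    I2: np.ndarray,
    from_pt: tuple[int, int],
    to_pt: tuple[int, int],
    x0: int,
    n: int,
    band_divisor: int = BAND_DIVISOR,
) -> TracedPath:
    """Endpoint-anchored DP along rows, restricted to the x0 +- n/10 band."""
    M = np.asarray(I2, dtype=float)
    fr, fc = int(from_pt[0]), int(from_pt[1])
    tr, tc = int(to_pt[0]), int(to_pt[1])
    if fr >= tr:
        raise TracingError("joint segment requires from_pt.row < to_pt.row")
    half = n // band_divisor
    lo, hi = x0 - half, x0 + half
    if not (lo <= fc <= hi and lo <= tc <= hi):
        logger.warning(
            "joint end points outside the x0+-n/%d band; widening band", band_divisor
        )
        lo, hi = min(lo, fc, tc), max(hi, fc, tc)
    lo = max(lo, 0)
    hi = min(hi, M.shape[1] - 1)
    if abs(tc - fc) > (tr - fr):
        raise TracingError(
            f"anchor {to_pt} not 3-connected-reachable from {from_pt}"
        )
    sub = M[:, lo : hi + 1]
    cum = cumulative_cost(sub, (fr, fc - lo), axis=0, direction=1, stop=tr)
    path = backtrack(cum, end=(tr, tc - lo))
    pts = path.points.copy()
    pts[:, 1] += lo
    total = float(M[pts[:, 0], pts[:, 1]].sum())
    return TracedPath(points=pts, axis=0, total_cost=total)


# ----------------------------------------------------------------------
# contour assembly
# ----------------------------------------------------------------------


def rasterize_closed_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed (row, col) polygon, boundary pixels included."""
    poly = np.asarray(poly, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _sk_polygon(poly[:, 0], poly[:, 1], shape=shape)
    mask[rr, cc] = True
    rr, cc = polygon_perimeter(
        np.round(poly[:, 0]).astype(int), np.round(poly[:, 1]).astype(int),
        shape=shape, clip=True,
    )
    mask[rr, cc] = True
    return mask


@dataclass
class URContours:
    """Two closed bone contours in original-image coordinates."""

    bone1: np.ndarray  # (L, 2) float, closed (first == last)
    bone2: np.ndarray
    masks: list[np.ndarray]
    components: list[TracedPath] = dataclass_field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "bone1": np.asarray(self.bone1).tolist(),
            "bone2": np.asarray(self.bone2).tolist(),
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "contours.json").write_text(json.dumps(self.to_json_dict()))
        for name, poly in (("bone1", self.bone1), ("bone2", self.bone2)):
            lines = [f"{r:.2f},{c:.2f}" for r, c in np.asarray(poly)]
            (directory / f"contour_{name}.csv").write_text("\n".join(lines) + "\n")
        from .image_io import save_png

        for i, m in enumerate(self.masks, start=1):
            save_png(directory / f"mask_bone{i}.png", m.astype(bool))


def _merge_bone_polygon(
    upper: TracedPath, joint: TracedPath, lower: TracedPath
) -> np.ndarray:
    """Concatenate upper (L->R) + joint (T->B) + lower (R->L) + proximal closure."""
    up = upper.points[np.argsort(upper.points[:, 1])]
    low = lower.points[np.argsort(lower.points[:, 1])]
    jt = joint.points

    # crossing check over shared columns
    common_lo = max(up[0, 1], low[0, 1])
    common_hi = min(up[-1, 1], low[-1, 1])
    up_rows = {c: r for r, c in up}
    for r, c in low:
        if common_lo <= c <= common_hi and up_rows.get(c, -np.inf) >= r:
            raise ContourAssemblyError(
                f"upper and lower diaphysis paths cross at column {c}", location=(r, c)
            )

    parts = [up]
    jt_trim = jt
    if np.array_equal(jt_trim[0], up[-1]):
        jt_trim = jt_trim[1:]
    if len(jt_trim) and np.array_equal(jt_trim[-1], low[-1]):
        jt_trim = jt_trim[:-1]
    parts.append(jt_trim)
    parts.append(low[::-1])

    # straight vertical closure at the leftmost traced column
    r_end, c_end = low[0]
    r_start, c_start = up[0]
    if c_end != c_start:
        raise ContourAssemblyError(
            "upper and lower paths end at different proximal columns",
            location=(int(r_end), int(c_end)),
        )
    if r_end - r_start > 1:
        closing_rows = np.arange(r_end - 1, r_start, -1)
        closure = np.stack([closing_rows, np.full_like(closing_rows, c_end)], axis=1)
        parts.append(closure)
    parts.append(up[:1])  # close the polygon
    return np.concatenate(parts, axis=0).astype(float)


def assemble_contours(
    paths: list[TracedPath],
    transform: StandardizationTransform,
    original_shape: tuple[int, int],
) -> URContours:
    """Merge 6 traced paths (upper/joint/lower per bone) into closed contours.

    ``paths`` order: [b1_upper, b1_joint, b1_lower, b2_upper, b2_joint,
    b2_lower].  Vertices are mapped through the inverse standardization
    transform into original-image coordinates and rasterized to masks.
    """
    if len(paths) != 6:
        raise ContourAssemblyError(f"expected 6 paths, got {len(paths)}")
    polys = []
    for k in (0, 3):
        poly_std = _merge_bone_polygon(paths[k], paths[k + 1], paths[k + 2])
        polys.append(transform.to_original(poly_std))
    masks = [rasterize_closed_polygon(p, original_shape) for p in polys]
    if (masks[0] & masks[1]).any():
        raise ContourAssemblyError("bone contours overlap after assembly")
    return URContours(bone1=polys[0], bone2=polys[1], masks=masks, components=list(paths))


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------


@dataclass
class SegmentConfig:
    preprocess: PreprocessConfig = dataclass_field(default_factory=PreprocessConfig)
    lambda1: float = 0.3
    lambda2: float = 0.7
    window: int = DEFAULT_WINDOW
    band_divisor: int = BAND_DIVISOR


def segment_image(
    image: Radiograph, config: SegmentConfig | None = None, return_intermediate: bool = False
):
    """Full pipeline: preprocess, seeds, cost maps, tracing, assembly.

    Returns :class:`URContours` (and the intermediate products when
    ``return_intermediate`` is set).  Deterministic for a fixed input.
    """
    config = config or SegmentConfig()
    pre = preprocess(image, config.preprocess)

    try:
        # the pre-dilation mask keeps the wrist-neck minimum unbiased
        proj_mask = pre.tissue_mask if pre.tissue_mask is not None else pre.forearm_mask
        x0, p_max = locate_distal_end(proj_mask)
        seedset = detect_seed_points(pre, x0)
    except SeedDetectionError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("seeds", exc) from exc

    # cost maps are built on the bilateral-denoised image: the gradient and
    # Canny terms are scale-normalized, and histogram equalization (useful
    # for seed prominence ranking) warps edge localization by a few pixels
    source = pre.smoothed_pixels if pre.smoothed_pixels is not None else pre.pixels
    maps = build_cost_maps(source, config.lambda1, config.lambda2)

    edges = []
    for seed in seedset.seeds:
        left = trace_diaphysis_edge(maps.I1, seed, -1, config.window, stop_col=0)
        right = trace_diaphysis_edge(maps.I1, seed, +1, config.window, stop_col=x0)
        pts = np.concatenate([left.points[::-1][:-1], right.points], axis=0)
        total = float(maps.I1[pts[:, 0], pts[:, 1]].sum())
        edges.append(TracedPath(points=pts, axis=1, total_cost=total))

    n = pre.pixels.shape[1]
    joints = []
    for k in (0, 2):
        up_end = tuple(edges[k].points[-1])
        low_end = tuple(edges[k + 1].points[-1])
        joints.append(
            trace_joint_segment(
                maps.I2, up_end, low_end, x0, n, band_divisor=config.band_divisor
            )
        )

    six = [edges[0], joints[0], edges[1], edges[2], joints[1], edges[3]]
    contours = assemble_contours(six, pre.transform, image.shape)
    if return_intermediate:
        return contours, {"pre": pre, "seeds": seedset, "maps": maps, "x0": x0, "p_max": p_max}
    return contours
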