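"""Synthetic forearm-radiograph phantoms with exact ground truth.

A phantom is two bright tapered bone bands inside a soft-tissue band that
necks down at the wrist and widens into a hand blob, over a smoothly
nonuniform background, with optional collimation borders, Gaussian noise,
variable orientation and exposure.  Geometry is generated in a canonical
left-to-right frame and rotated last; ground-truth masks and contours are
stored in the final orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .image_io import Radiograph, to_radiograph
from .transform import rotate_points_cw, unrotate_points_cw

__all__ = ["PhantomParams", "PhantomTruth", "generate_phantom", "generate_suite", "ORIENTATIONS"]

# number of clockwise quarter turns applied to the canonical (wrist-at-right) frame
ORIENTATIONS = {"left-right": 0, "down": 1, "right-left": 2, "up": 3}


@dataclass(frozen=True)
class PhantomParams:
    shape: tuple[int, int] = (704, 768)
    collimation: int = 16
    bone_centers: tuple[float, float] = (300.0, 404.0)
    bone_halfwidth: float = 22.0
    taper: float = 0.12
    flare: float = 5.0
    flare_sigma: float = 35.0
    wrist_col: int = 580
    cap_depth: float = 6.0
    bone_end_offset: int = 5  # bone tip sits this many columns before the wrist neck
    soft_center: float = 352.0
    soft_half: float = 150.0
    neck_half: float = 110.0
    neck_sigma: float = 35.0
    hand_half: float = 215.0
    hand_extent: int = 150
    bg_base: float = 0.07
    soft_level: float = 0.38
    bone_level: float = 0.75
    bg_gradient: float = 0.12
    edge_blur: float = 0.8
    skin_blur: float = 2.5  # skin line is softer than cortical bone edges
    soft_texture: float = 0.10  # smooth intra-tissue intensity variation
    bone_texture: float = 0.05
    texture_scale: float = 14.0  # correlation length of the texture fields (px)
    noise_sigma: float = 0.03
    exposure: float = 1.0
    orientation: str = "left-right"
    seed: int = 0

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not (self.bg_base < self.soft_level < self.bone_level):
            raise ValueError("intensity levels must satisfy background < soft tissue < bone")
        h, w = self.shape
        if self.wrist_col + self.hand_extent >= w - self.collimation:
            raise ValueError("hand extends into the collimation border")
        lo = min(self.bone_centers) - self.bone_halfwidth - self.flare
        hi = max(self.bone_centers) + self.bone_halfwidth + self.flare
        if lo <= self.soft_center - self.neck_half or hi >= self.soft_center + self.neck_half:
            raise ValueError("bone bands are not inside the soft-tissue band")
        gap = abs(self.bone_centers[1] - self.bone_centers[0])
        if gap <= 2 * (self.bone_halfwidth + self.flare):
            raise ValueError("bone bands overlap")


@dataclass
class PhantomTruth:
    """Phantom image plus exact geometry, in the final orientation."""

    image: Radiograph
    bone_masks: list[np.ndarray]
    bone_contours: list[np.ndarray]
    soft_tissue_mask: np.ndarray
    wrist_column: int
    params: PhantomParams
    rot_k: int
    canonical_shape: tuple[int, int]
    _edges: np.ndarray = field(repr=False, default=None)  # (2, 2, W) top/bottom per bone
    _bone_cols: np.ndarray = field(repr=False, default=None)  # (2, 2) start/end col per bone

    def edge_rows(self, col: int) -> tuple[int, int, int, int]:
        """Canonical-frame bone edge rows (b1_top, b1_bottom, b2_top, b2_bottom) at ``col``."""
        return (
            int(self._edges[0, 0, col]),
            int(self._edges[0, 1, col]),
            int(self._edges[1, 0, col]),
            int(self._edges[1, 1, col]),
        )

    def to_canonical_points(self, points: np.ndarray) -> np.ndarray:
        """Map final-orientation (row, col) points back to the canonical frame."""
        return unrotate_points_cw(points, self.rot_k, self.canonical_shape)

    def to_final_points(self, points: np.ndarray) -> np.ndarray:
        """Map canonical-frame (row, col) points to the final orientation."""
        return rotate_points_cw(points, self.rot_k, self.canonical_shape)

    @property
    def canonical_bone_masks(self) -> list[np.ndarray]:
        return [np.rot90(m, self.rot_k) for m in self.bone_masks]

    @property
    def canonical_soft_mask(self) -> np.ndarray:
        return np.rot90(self.soft_tissue_mask, self.rot_k)


def _bone_geometry(p: PhantomParams, center: float, width: int):
    """Integer top/bottom edge rows per column for one bone band."""
    c0 = p.collimation
    cols = np.arange(width, dtype=float)
    span = max(p.wrist_col - c0, 1)
    h = p.bone_halfwidth * (1.0 - p.taper * (cols - c0) / span)
    h = h + p.flare * np.exp(-(((cols - p.wrist_col) / p.flare_sigma) ** 2))
    h_end = p.bone_halfwidth * (1.0 - p.taper) + p.flare
    # steep rounded cap ending a few columns before the wrist neck
    tip = p.wrist_col - p.bone_end_offset
    cap = h_end * np.sqrt(np.maximum((tip - cols) / max(p.cap_depth, 1e-9), 0.0))
    half = np.minimum(h, cap)
    half[(cols < c0) | (cols > tip)] = -1.0
    top = np.round(center - half).astype(int)
    bottom = np.round(center + half).astype(int)
    valid = half >= 0
    return top, bottom, valid


def _column_fill(top: np.ndarray, bottom: np.ndarray, valid: np.ndarray, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rows = np.arange(shape[0])[:, None]
    sel = valid[None, :] & (rows >= top[None, :]) & (rows <= bottom[None, :])
    return mask | sel


def _densify_chain(rows: np.ndarray, cols: np.ndarray, is_top: bool) -> list:
    """Boundary chain with intermediate vertices where the edge is steep.

    When consecutive per-column edge rows differ by more than one, the mask
    boundary runs vertically inside one of the two columns; inserting those
    pixels keeps the rasterized polygon identical to the column-fill mask.
    For the top edge the run lies in the earlier column when rows increase;
    for the bottom edge it is the other way around.
    """
    chain = [(int(rows[0]), int(cols[0]))]
    for (r0, c0), (r1, c1) in zip(zip(rows[:-1], cols[:-1]), zip(rows[1:], cols[1:])):
        r0, c0, r1, c1 = int(r0), int(c0), int(r1), int(c1)
        step = 1 if r1 > r0 else -1
        if abs(r1 - r0) > 1:
            run_col = c0 if (step > 0) == is_top else c1
            for r in range(r0 + step, r1, step):
                chain.append((r, run_col))
        chain.append((r1, c1))
    return chain


def _contour_from_edges(top: np.ndarray, bottom: np.ndarray, valid: np.ndarray) -> np.ndarray:
    cols = np.flatnonzero(valid)
    upper = _densify_chain(top[cols], cols, is_top=True)
    lower = _densify_chain(bottom[cols[::-1]], cols[::-1], is_top=False)
    poly = np.array(upper + lower + upper[:1], dtype=float)
    return poly


def _soft_half_profile(p: PhantomParams, width: int) -> np.ndarray:
    c0 = p.collimation
    hand_center = p.wrist_col + int(round(0.5 * p.hand_extent))
    hand_end = p.wrist_col + p.hand_extent
    xs = [c0, 0.5 * (c0 + p.wrist_col), p.wrist_col - 2 * p.neck_sigma,
          p.wrist_col, hand_center, hand_end]
    ys = [p.soft_half, p.soft_half, p.soft_half, p.neck_half, p.hand_half, 0.0]
    xs, ys = zip(*sorted(set(zip(xs, ys))))
    interp = PchipInterpolator(np.array(xs, float), np.array(ys, float))
    cols = np.arange(width, dtype=float)
    half = interp(np.clip(cols, xs[0], xs[-1]))
    half[(cols < c0) | (cols > hand_end)] = -1.0
    return half


def generate_phantom(params: PhantomParams | None = None) -> PhantomTruth:
    """Render a phantom and its exact ground truth (deterministic per seed)."""
    p = params or PhantomParams()
    rng = np.random.default_rng(p.seed)
    H, W = p.shape

    # --- geometry (canonical frame) -------------------------------------
    edges = np.zeros((2, 2, W), dtype=int)
    bone_masks = []
    bone_contours = []
    bone_cols = np.zeros((2, 2), dtype=int)
    bone_union = np.zeros((H, W), dtype=bool)
    for b, center in enumerate(p.bone_centers):
        top, bottom, valid = _bone_geometry(p, center, W)
        edges[b, 0], edges[b, 1] = top, bottom
        mask = _column_fill(top, bottom, valid, (H, W))
        bone_masks.append(mask)
        bone_contours.append(_contour_from_edges(top, bottom, valid))
        cols = np.flatnonzero(valid)
        bone_cols[b] = (cols[0], cols[-1])
        bone_union |= mask

    half = _soft_half_profile(p, W)
    soft_top = np.round(p.soft_center - half).astype(int)
    soft_bottom = np.round(p.soft_center + half).astype(int)
    soft_valid = half >= 0
    soft_mask = _column_fill(
        np.clip(soft_top, p.collimation, None),
        np.clip(soft_bottom, None, H - p.collimation - 1),
        soft_valid,
        (H, W),
    )
    soft_mask |= bone_union  # bones are always tissue

    # --- rendering ------------------------------------------------------
    # layered render: the skin line gets a wider blur than the bone edges so
    # the dominant vertical-gradient peaks sit on the diaphysis edges
    soft_layer = soft_mask.astype(float)
    if p.skin_blur > 0:
        soft_layer = gaussian_filter(soft_layer, p.skin_blur)
    bone_layer = bone_union.astype(float)
    if p.edge_blur > 0:
        bone_layer = gaussian_filter(bone_layer, p.edge_blur)
    def _texture(amp: float) -> float | np.ndarray:
        if amp <= 0:
            return 1.0
        t = gaussian_filter(rng.normal(size=(H, W)), p.texture_scale)
        return 1.0 + amp * t / (np.abs(t).max() + 1e-12)

    img = (
        p.bg_base
        + (p.soft_level - p.bg_base) * soft_layer * _texture(p.soft_texture)
        + (p.bone_level - p.soft_level) * bone_layer * _texture(p.bone_texture)
    )

    if p.bg_gradient > 0:
        gy, gx = np.meshgrid(np.linspace(-1, 1, H), np.linspace(-1, 1, W), indexing="ij")
        a, b_, c_ = rng.uniform(-1, 1, 3)
        blob = gaussian_filter(rng.normal(size=(H, W)), min(H, W) / 6)
        blob = blob / (np.abs(blob).max() + 1e-12)
        plane = a * gy + b_ * gx + 0.7 * c_ * blob
        plane = plane / (np.abs(plane).max() + 1e-12)
        img = img * (1.0 + p.bg_gradient * plane)

    if p.exposure != 1.0:
        img = p.bg_base + (img - p.bg_base) * p.exposure

    if p.collimation > 0:
        cw = p.collimation
        frame = np.zeros((H, W), dtype=bool)
        frame[:cw], frame[-cw:], frame[:, :cw], frame[:, -cw:] = True, True, True, True
        img[frame] = 0.0

    if p.noise_sigma > 0:
        img = img + rng.normal(0.0, p.noise_sigma, size=(H, W))
    img = np.clip(img, 0.0, 1.0)

    # --- orientation ----------------------------------------------------
    k = ORIENTATIONS[p.orientation]
    image = to_radiograph(np.ascontiguousarray(np.rot90(img, -k)))
    return PhantomTruth(
        image=image,
        bone_masks=[np.ascontiguousarray(np.rot90(m, -k)) for m in bone_masks],
        bone_contours=[rotate_points_cw(c, k, (H, W)) for c in bone_contours],
        soft_tissue_mask=np.ascontiguousarray(np.rot90(soft_mask, -k)),
        wrist_column=p.wrist_col,
        params=p,
        rot_k=k,
        canonical_shape=(H, W),
        _edges=edges,
        _bone_cols=bone_cols,
    )


def suite_params(n: int, master_seed: int) -> list[PhantomParams]:
    """Jittered parameter sets covering all orientations and both exposure regimes."""
    rng = np.random.default_rng(master_seed)
    names = list(ORIENTATIONS)
    out = []
    for i in range(n):
        low_exposure = (i % 3) == 2  # ~1/3 low-exposure
        base = PhantomParams(
            bone_centers=(
                300.0 + rng.uniform(-12, 12),
                404.0 + rng.uniform(-12, 12),
            ),
            bone_halfwidth=float(rng.uniform(19, 26)),
            taper=float(rng.uniform(0.08, 0.16)),
            flare=float(rng.uniform(3, 7)),
            wrist_col=int(rng.integers(545, 596)),
            soft_center=352.0 + rng.uniform(-10, 10),
            bg_gradient=float(rng.uniform(0.05, 0.18)),
            collimation=int(rng.choice([0, 12, 20])),
            noise_sigma=0.08 if low_exposure else 0.03,
            exposure=0.6 if low_exposure else 1.0,
            orientation=names[i % 4],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(base)
    return out


def generate_suite(n: int, master_seed: int) -> list[PhantomTruth]:
    """Generate ``n`` phantoms, reproducible from ``master_seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(p) for p in suite_params(n, master_seed)]


def exposure_regime(params: PhantomParams) -> str:
    return "low" if params.exposure < 1.0 else "normal"


def michelson_contrast(truth: PhantomTruth) -> float:
    """Bone vs soft-tissue Michelson contrast measured from the stored masks."""
    img = truth.image.pixels
    bones = truth.bone_masks[0] | truth.bone_masks[1]
    soft_only = truth.soft_tissue_mask & ~bones
    b = float(img[bones].mean())
    s = float(img[soft_only].mean())
    return (b - s) / (b + s)
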