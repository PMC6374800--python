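"""Geometric bookkeeping between the standardized frame and the original image.

The standardization pipeline applies, in order: a crop, a bilinear rescale,
and a rotation by a multiple of 90 degrees.  ``StandardizationTransform``
stores the three pieces and maps point coordinates (row, col) in either
direction.  Points are pixel-center coordinates, 0-based, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StandardizationTransform", "rotate_points_cw", "unrotate_points_cw"]


def rotate_points_cw(points: np.ndarray, k: int, shape: tuple[int, int]) -> np.ndarray:
    """Rotate (row, col) points by ``k`` quarter turns clockwise.

    ``shape`` is the shape of the array the points live in *before* the
    rotation.  Matches ``np.rot90(a, -k)`` pixel-for-pixel.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2).copy()
    h, w = shape
    for _ in range(k % 4):
        r, c = pts[:, 0].copy(), pts[:, 1].copy()
        # one cw turn: (r, c) in (h, w) -> (c, h-1-r) in (w, h)
        pts[:, 0] = c
        pts[:, 1] = h - 1 - r
        h, w = w, h
    return pts


def unrotate_points_cw(points: np.ndarray, k: int, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`rotate_points_cw`; ``shape`` is the pre-rotation shape."""
    k = k % 4
    # shape after k turns
    h, w = shape
    if k % 2 == 1:
        h, w = w, h
    pts = np.asarray(points, dtype=float).reshape(-1, 2).copy()
    for _ in range(k):
        r, c = pts[:, 0].copy(), pts[:, 1].copy()
        # inverse of one cw turn applied to an (h', w') array whose source was (w', h')
        pts[:, 0] = w - 1 - c
        pts[:, 1] = r
        h, w = w, h
    return pts


@dataclass
class StandardizationTransform:
    """Affine map between standardized and original pixel coordinates.

    Attributes
    ----------
    crop_box : (r0, c0, r1, c1)
        Half-open crop box in original coordinates.
    scale : (sr, sc)
        Per-axis scale factors of the rescale step, ``out_dim / in_dim``.
    rot_k_cw : int
        Number of clockwise quarter turns applied after the rescale.
    scaled_shape : (h, w)
        Shape of the rescaled image *before* rotation.
    """

    crop_box: tuple[int, int, int, int]
    scale: tuple[float, float] = (1.0, 1.0)
    rot_k_cw: int = 0
    scaled_shape: tuple[int, int] = (0, 0)
    inverted: bool = field(default=False)

    @property
    def rotation_deg(self) -> int:
        return (self.rot_k_cw % 4) * 90

    def to_original(self, points) -> np.ndarray:
        """Map standardized (row, col) points to original-image coordinates."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        pts = unrotate_points_cw(pts, self.rot_k_cw, self.scaled_shape)
        sr, sc = self.scale
        out = np.empty_like(pts)
        # bilinear-resize convention: centers align, out = (in + .5)*s - .5
        out[:, 0] = (pts[:, 0] + 0.5) / sr - 0.5 + self.crop_box[0]
        out[:, 1] = (pts[:, 1] + 0.5) / sc - 0.5 + self.crop_box[1]
        return out

    def to_standardized(self, points) -> np.ndarray:
        """Map original-image (row, col) points to standardized coordinates."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        sr, sc = self.scale
        out = np.empty_like(pts)
        out[:, 0] = (pts[:, 0] - self.crop_box[0] + 0.5) * sr - 0.5
        out[:, 1] = (pts[:, 1] - self.crop_box[1] + 0.5) * sc - 0.5
        return rotate_points_cw(out, self.rot_k_cw, self.scaled_shape)

    def to_json_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg,
            "crop_box": list(self.crop_box),
            "ratio": [self.scale[0], self.scale[1]],
            "scaled_shape": list(self.scaled_shape),
            "inverted": self.inverted,
        }
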