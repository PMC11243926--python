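"""Planar homography between the RGB and thermal panels.

The two cameras view the same (approximately planar) box floor from
nearby viewpoints, so a 3x3 projective transform fitted from four point
correspondences — the corners of the box visible in both panels — maps any
RGB-panel pixel to its thermal-panel counterpart.

The matrix is found by solving the standard 8-unknown linear system: with
m22 fixed at 1, each correspondence (x, y) -> (u, v) contributes

    u = (m00 x + m01 y + m02) / (m20 x + m21 y + 1)
    v = (m10 x + m11 y + m12) / (m20 x + m21 y + 1)

i.e. two linear equations, giving 8 equations for 8 unknowns from four
points.  Mapped coordinates are normalised by the homogeneous w and rounded
with floor(v + 0.5) to land on an integer thermal pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MappingError, OutOfPanelError, SingularQuadError
from .mask_pixel import PixelCoord

__all__ = ["QuadCorrespondence", "Homography", "fit_homography", "map_point", "rect_quad"]

Point = tuple[float, float]


def rect_quad(x_min: float, y_min: float, x_max: float, y_max: float) -> list[Point]:
    """Corners of an axis-aligned rectangle in the fixed calibration order:
    top-left, top-right, bottom-right, bottom-left."""
    return [(x_min, y_min), (x_max, y_min), (x_max, y_max), (x_min, y_max)]


def _has_collinear_triple(quad: Sequence[Point], tol: float = 1e-9) -> bool:
    for i in range(4):
        pts = [quad[j] for j in range(4) if j != i]
        (x1, y1), (x2, y2), (x3, y3) = pts
        cross = (x2 - x1) * (y3 - y1) - (y2 - y1) * (x3 - x1)
        if abs(cross) <= tol:
            return True
    return False


@dataclass(frozen=True)
class QuadCorrespondence:
    """Four calibration points per panel, in matching corner order."""

    src: tuple[Point, Point, Point, Point]
    dst: tuple[Point, Point, Point, Point]

    def __post_init__(self):
        if len(self.src) != 4 or len(self.dst) != 4:
            raise ValueError("src and dst must each have exactly 4 points")
        for name, quad in (("src", self.src), ("dst", self.dst)):
            if _has_collinear_triple(quad):
                raise SingularQuadError(f"{name} quad has three collinear points")

    @classmethod
    def from_rects(cls, src_rect: Sequence[float], dst_rect: Sequence[float]) -> "QuadCorrespondence":
        """Rectangle-to-rectangle correspondence from (x_min, y_min, x_max, y_max)."""
        return cls(tuple(rect_quad(*src_rect)), tuple(rect_quad(*dst_rect)))


@dataclass(frozen=True)
class Homography:
    """3x3 projective map, normalised so m[2, 2] == 1."""

    m: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(m[2, 2]) < 1e-12:
            raise SingularQuadError("m[2][2] is zero; cannot normalise")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) <= 1e-12:
            raise SingularQuadError("homography matrix is singular")
        object.__setattr__(self, "m", m)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.m))

    def to_text(self) -> str:
        """Nine numbers, row-major, for the cached-matrix text format."""
        return " ".join(repr(float(v)) for v in self.m.ravel())

    @classmethod
    def from_text(cls, text: str) -> "Homography":
        vals = [float(v) for v in text.split()]
        if len(vals) != 9:
            raise ValueError(f"expected 9 numbers, got {len(vals)}")
        return cls(np.array(vals).reshape(3, 3))


def fit_homography(corr: QuadCorrespondence) -> Homography:
    """Fit the 3x3 transform taking each src corner to its dst corner.

    Solves the 8x8 linear system directly; the four corner reprojections
    agree with dst to well below 1e-6 px for non-degenerate quads.
    """
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(corr.src, corr.dst)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i] = u
        b[2 * i + 1] = v
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SingularQuadError(f"degenerate correspondence: {exc}") from exc
    m = np.append(sol, 1.0).reshape(3, 3)
    return Homography(m)


def map_point(
    h: Homography,
    p: PixelCoord,
    panel_shape: tuple[int, int] | None = None,
) -> PixelCoord:
    """Map an RGB-panel pixel into the thermal panel.

    Computes m @ (x, y, 1), divides by the homogeneous w, and rounds each
    coordinate as floor(v + 0.5).  Negative results are never rounded into
    the panel: with ``panel_shape`` (height, width) given, any coordinate
    outside [0, width) x [0, height) raises :class:`OutOfPanelError`
    carrying the raw (unrounded) coordinates; without it, only negative
    results raise.
    """
    vec = h.m @ np.array([p.x, p.y, 1.0])
    w = vec[2]
    if abs(w) < 1e-12:
        raise MappingError(f"point ({p.x}, {p.y}) maps to infinity (w = {w})")
    xr, yr = vec[0] / w, vec[1] / w
    xn = math.floor(xr + 0.5)
    yn = math.floor(yr + 0.5)
    if panel_shape is not None:
        ph, pw = panel_shape
        if not (0 <= xn < pw and 0 <= yn < ph):
            raise OutOfPanelError(xr, yr)
    elif xn < 0 or yn < 0:
        raise OutOfPanelError(xr, yr)
    return PixelCoord(xn, yn)
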