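"""Mask refinement inside a bounding box and representative-pixel selection.

A detector's bounding box contains both the animal and background.  The
measurement must come from the animal, so each box is refined to a binary
mask — the lizard is darker than the light box floor, so an inverse-binary
threshold on the grayscale box marks foreground white (255) and background
black (0) — and a single representative pixel is picked per box:

1. paint a black mask the size of the RGB panel;
2. whiten the bounding-box region;
3. AND the mask with the panel to isolate the box contents;
4. convert to grayscale;
5. inverse-binary threshold: gray <= threshold -> white (foreground).

The box centre is used when it lands on foreground; otherwise the nearest
foreground pixel (Euclidean distance, ties by row-major scan order) takes
its place.  A curled tail is the classic case: the box centre falls on
background between body and tail tip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, NoForegroundError
from .frame_io import Rect

__all__ = [
    "PixelCoord",
    "grayscale",
    "refine_box_mask",
    "nearest_white_pixel",
    "representative_pixel",
]

DEFAULT_GRAY_THRESHOLD = 128

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PixelCoord:
    x: int
    y: int


def grayscale(image: np.ndarray) -> np.ndarray:
    """Luma grayscale (0.299 R + 0.587 G + 0.114 B), rounded to uint8."""
    if image.ndim == 2:
        return image.astype(np.uint8)
    gray = image[..., :3].astype(np.float64) @ _LUMA
    return np.floor(gray + 0.5).astype(np.uint8)


def refine_box_mask(roi: np.ndarray, box: Rect, gray_threshold: int = DEFAULT_GRAY_THRESHOLD) -> np.ndarray:
    """Binary foreground mask over the whole panel, white only inside ``box``.

    Inside the box, pixels with grayscale value <= ``gray_threshold`` become
    255 (dark animal on light background), the rest 0; everything outside
    the box stays 0.
    """
    if not 0 <= gray_threshold <= 255:
        raise ValueError(f"gray_threshold must be in [0, 255], got {gray_threshold}")
    h, w = roi.shape[:2]
    if box.x2 > w or box.y2 > h:
        raise BoundsError(f"box {box} exceeds panel extent {w}x{h}")
    mask = np.zeros((h, w), dtype=np.uint8)
    patch = grayscale(roi[box.y : box.y2, box.x : box.x2])
    mask[box.y : box.y2, box.x : box.x2] = np.where(patch <= gray_threshold, 255, 0)
    return mask


def nearest_white_pixel(mask: np.ndarray, start: PixelCoord) -> PixelCoord:
    """White pixel minimising Euclidean distance to ``start``.

    Ties break by row-major scan order (smallest y, then smallest x), which
    makes the choice deterministic.
    """
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise NoForegroundError("mask contains no white pixel")
    d2 = (ys.astype(np.int64) - start.y) ** 2 + (xs.astype(np.int64) - start.x) ** 2
    # np.nonzero yields row-major order, so the first minimum is the
    # smallest-y (then smallest-x) pixel among equidistant candidates.
    i = int(np.argmin(d2))
    return PixelCoord(int(xs[i]), int(ys[i]))


def representative_pixel(mask: np.ndarray, box: Rect) -> PixelCoord:
    """Pick the single pixel that stands for a bounding box.

    The integer box centre if the mask is white there; otherwise the
    nearest white pixel searched within the box only — foreground outside
    the box belongs to other detections and must not be selected.

    Raises :class:`NoForegroundError` when the box holds no white pixel at
    all (measurement is then logged as missing for that detection).
    """
    h, w = mask.shape[:2]
    if box.x2 > w or box.y2 > h:
        raise BoundsError(f"box {box} exceeds mask extent {w}x{h}")
    cx, cy = box.centre
    if mask[cy, cx] == 255:
        return PixelCoord(cx, cy)
    sub = mask[box.y : box.y2, box.x : box.x2]
    local = nearest_white_pixel(sub, PixelCoord(cx - box.x, cy - box.y))
    return PixelCoord(local.x + box.x, local.y + box.y)
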