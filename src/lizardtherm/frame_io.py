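"""Loading composite frames and carving out the RGB and thermal panels.

The recording rig screen-captures both cameras side by side into one
composite image: RGB view on the left, thermal view (with its colour
scale bar) on the right.  Everything downstream works on the two panels,
which are plain rectangular regions of interest cut out of the composite.

Coordinates are 0-based, ``(x = column, y = row)``, y increasing downward,
with half-open extents ``[y, y + height) x [x, x + width)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .errors import BoundsError, InputError

__all__ = ["Rect", "FramePair", "extract_roi", "paste_roi", "split_side_by_side", "iter_frames"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle: top-left corner plus size."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"Rect size must be positive, got {self.width}x{self.height}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"Rect corner must be non-negative, got ({self.x}, {self.y})")

    @property
    def x2(self) -> int:
        """One past the right edge."""
        return self.x + self.width

    @property
    def y2(self) -> int:
        """One past the bottom edge."""
        return self.y + self.height

    @property
    def centre(self) -> tuple[int, int]:
        """Integer centre pixel (floor division for even sizes)."""
        return (self.x + self.width // 2, self.y + self.height // 2)

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, other: "Rect") -> bool:
        return (
            self.x <= other.x
            and self.y <= other.y
            and other.x2 <= self.x2
            and other.y2 <= self.y2
        )


@dataclass(frozen=True)
class FramePair:
    """One composite frame split into its two camera panels."""

    rgb_panel: np.ndarray
    thermal_panel: np.ndarray
    frame_index: int
    timestamp: datetime

    def __post_init__(self):
        if self.rgb_panel.size == 0 or self.thermal_panel.size == 0:
            raise ValueError("panels must be non-empty")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


def _check_inside(image: np.ndarray, rect: Rect) -> None:
    h, w = image.shape[:2]
    if rect.x2 > w:
        raise BoundsError(
            f"rect right edge {rect.x2} exceeds image width {w}"
        )
    if rect.y2 > h:
        raise BoundsError(
            f"rect bottom edge {rect.y2} exceeds image height {h}"
        )


def extract_roi(image: np.ndarray, rect: Rect) -> np.ndarray:
    """Cut ``image[y : y + height, x : x + width]`` out of a composite.

    Returns a copy so the caller can paint on panels without touching the
    source frame.
    """
    _check_inside(image, rect)
    return image[rect.y : rect.y2, rect.x : rect.x2].copy()


def paste_roi(image: np.ndarray, rect: Rect, roi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`extract_roi`: write ``roi`` back at ``rect``."""
    _check_inside(image, rect)
    if roi.shape[:2] != (rect.height, rect.width):
        raise ValueError("roi shape does not match rect size")
    out = image.copy()
    out[rect.y : rect.y2, rect.x : rect.x2] = roi
    return out


def split_side_by_side(
    image: np.ndarray,
    rgb_rect: Rect,
    thermal_rect: Rect,
    frame_index: int = 0,
    timestamp: datetime | None = None,
) -> FramePair:
    """Split a side-by-side composite into its RGB and thermal panels.

    The two rectangles come from a one-off calibration of the recording
    layout (where each camera's view sits inside the screen capture); they
    may overlap.
    """
    if timestamp is None:
        timestamp = datetime.now()
    return FramePair(
        rgb_panel=extract_roi(image, rgb_rect),
        thermal_panel=extract_roi(image, thermal_rect),
        frame_index=frame_index,
        timestamp=timestamp,
    )


def iter_frames(
    source: str | Path, stride: int = 1
) -> Iterator[tuple[int, datetime, np.ndarray]]:
    """Yield every ``stride``-th frame of an image or video file.

    A still image yields a single frame with index 0.  For multi-frame
    sources the per-frame timestamp is the file's modification time plus
    ``frame_index / fps`` seconds (fps from metadata when present, else
    1 fps).
    """
    path = Path(source)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if not path.exists():
        raise InputError(f"source does not exist: {path}")
    base_time = datetime.fromtimestamp(os.path.getmtime(path))

    if path.suffix.lower() in _IMAGE_SUFFIXES:
        try:
            frame = iio.imread(path)
        except Exception as exc:  # decoder-specific exception types vary
            raise InputError(f"cannot decode image {path}: {exc}") from exc
        yield 0, base_time, np.asarray(frame)
        return

    try:
        meta = iio.immeta(path)
        fps = float(meta.get("fps", 0)) or 1.0
    except Exception:
        fps = 1.0
    try:
        for index, frame in enumerate(iio.imiter(path)):
            if index % stride == 0:
                ts = base_time + timedelta(seconds=index / fps)
                yield index, ts, np.asarray(frame)
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"cannot decode video {path}: {exc}") from exc


def legacy_stride(fps: float, cadence_s: float = 20.0) -> int:
    """Frame stride matching the manual workflow's fixed measurement cadence.

    The hand-clicking protocol this tool replaces sampled the video every
    20 s; ``stride = round(cadence * fps)`` reproduces that sampling rate.
    """
    return max(1, round(cadence_s * fps))
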