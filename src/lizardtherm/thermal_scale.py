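"""Colour-scale-bar model: turning a thermal pixel's colour into degrees.

The thermal camera's screen output is false colour plus a vertical scale
bar annotated with the frame's minimum and maximum temperatures.  The bar
is the only temperature calibration available (no radiometric data), so a
pixel's temperature is read in two steps: find the bar row whose colour is
closest to the pixel's colour, then linearly interpolate that row's
position between the bar ends:

    T = t_min + (y_max - final) / (y_max - y_min) * (t_max - t_min)

where ``final`` is the row index, ``y_min`` the top (hot) end and ``y_max``
the bottom (cold) end of the bar.  The bar is nominally 10 px wide; colours
are averaged across the width to suppress screen-capture compression
artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, RangeError
from .mask_pixel import PixelCoord

__all__ = ["ScaleBar", "BarSample", "row_to_temperature", "sample_bar", "colour_to_temperature"]

DEFAULT_BAR_WIDTH = 10


@dataclass(frozen=True)
class ScaleBar:
    """Calibration parameters of the embedded colour scale bar.

    ``t_min``/``t_max`` are the printed end temperatures in deg C;
    ``y_min``/``y_max`` the pixel rows of the bar's top (hot) and bottom
    (cold) corners; ``x_med`` the column of the bar centre.  All pixel
    values are in thermal-panel coordinates and read off the image by the
    user, the same way the printed temperatures are.
    """

    t_min: float
    t_max: float
    y_min: int
    y_max: int
    x_med: int
    bar_width: int = DEFAULT_BAR_WIDTH

    def __post_init__(self):
        if self.t_max <= self.t_min:
            raise ValueError(f"t_max must exceed t_min ({self.t_max} <= {self.t_min})")
        if self.y_max <= self.y_min:
            raise ValueError(f"y_max must exceed y_min ({self.y_max} <= {self.y_min})")
        if self.bar_width < 1:
            raise ValueError(f"bar_width must be >= 1, got {self.bar_width}")

    @property
    def n_rows(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def step(self) -> float:
        """Temperature quantisation step per bar row, deg C."""
        return (self.t_max - self.t_min) / (self.y_max - self.y_min)

    def columns(self) -> tuple[int, int]:
        """Half-open column extent of the bar footprint."""
        x0 = self.x_med - self.bar_width // 2
        return x0, x0 + self.bar_width


@dataclass(frozen=True)
class BarSample:
    """Per-row mean colours read off a rendered scale bar."""

    rows: np.ndarray      # (n,) int row indices, strictly increasing
    colours: np.ndarray   # (n, 3) uint8


def row_to_temperature(bar: ScaleBar, final: int) -> float:
    """Linear interpolation of a bar row's position into deg C.

    The top row (``y_min``) is the hot end (t_max), the bottom row
    (``y_max``) the cold end (t_min).
    """
    if not bar.y_min <= final <= bar.y_max:
        raise RangeError(f"row {final} outside bar extent [{bar.y_min}, {bar.y_max}]")
    return bar.t_min + (bar.y_max - final) / (bar.y_max - bar.y_min) * (bar.t_max - bar.t_min)


def sample_bar(thermal: np.ndarray, bar: ScaleBar) -> BarSample:
    """Read one mean colour per bar row from the thermal panel.

    Each row's colour is the arithmetic mean over the bar's width, every
    channel rounded half-up to 8-bit.
    """
    h, w = thermal.shape[:2]
    x0, x1 = bar.columns()
    if x0 < 0 or x1 > w or bar.y_min < 0 or bar.y_max >= h:
        raise BoundsError(
            f"bar footprint cols [{x0}, {x1}) rows [{bar.y_min}, {bar.y_max}] "
            f"outside panel {w}x{h}"
        )
    strip = thermal[bar.y_min : bar.y_max + 1, x0:x1, :3].astype(np.float64)
    mean = strip.mean(axis=1)
    colours = np.floor(mean + 0.5).astype(np.uint8)
    rows = np.arange(bar.y_min, bar.y_max + 1)
    return BarSample(rows=rows, colours=colours)


def colour_to_temperature(thermal: np.ndarray, bar: ScaleBar, p: PixelCoord) -> float:
    """Temperature of a thermal-panel pixel via nearest bar colour.

    Matches the pixel's RGB colour to the sampled bar row minimising
    Euclidean distance (ties -> smaller row index, i.e. the hotter row),
    then interpolates that row's position.  The result always lies in
    [t_min, t_max].
    """
    h, w = thermal.shape[:2]
    if not (0 <= p.x < w and 0 <= p.y < h):
        raise BoundsError(f"pixel ({p.x}, {p.y}) outside thermal panel {w}x{h}")
    sample = sample_bar(thermal, bar)
    colour = thermal[p.y, p.x, :3].astype(np.float64)
    d2 = ((sample.colours.astype(np.float64) - colour) ** 2).sum(axis=1)
    best = int(np.argmin(d2))  # argmin takes the first = smallest row on ties
    return row_to_temperature(bar, int(sample.rows[best]))
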