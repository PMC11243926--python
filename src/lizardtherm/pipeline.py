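"""End-to-end orchestration: frame -> detections -> pixels -> temperatures -> log.

For every frame the steps are: detect body parts in the RGB panel, drop
low-confidence boxes, refine each box to a foreground mask and pick its
representative pixel, map that pixel into the thermal panel through the
calibration homography, and read the temperature off the colour scale
bar.  A detection that fails a step (no foreground in its box, or a pixel
mapping outside the thermal panel) yields a Measurement with the matching
status instead of aborting the frame — every surviving detection produces
exactly one log line, so nothing is dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

import yaml

from .detection import ClassLabel, Detector, detect, filter_detections
from .errors import ConfigError, NoForegroundError, OutOfPanelError
from .frame_io import FramePair, Rect
from .mask_pixel import PixelCoord, refine_box_mask, representative_pixel
from .registration import Homography, QuadCorrespondence, fit_homography, map_point
from .thermal_scale import ScaleBar, colour_to_temperature

__all__ = ["Measurement", "PipelineConfig", "process_frame", "write_log", "read_log"]

STATUS_OK = "ok"
STATUS_NO_FOREGROUND = "no_foreground"
STATUS_OUT_OF_PANEL = "out_of_panel"

_REQUIRED_KEYS = ("rgb_roi", "thermal_roi", "src_quad", "dst_quad", "scalebar")
_REQUIRED_SCALEBAR_KEYS = ("t_min", "t_max", "y_min", "y_max", "x_med")


@dataclass(frozen=True)
class Measurement:
    """One logged temperature reading (or recorded failure) per detection."""

    date: str          # YYYY-MM-DD
    time: str          # HH:MM:SS
    label: ClassLabel
    rgb_pixel: PixelCoord | None
    thermal_pixel: PixelCoord | None
    temperature_c: float | None
    status: str

    def __post_init__(self):
        if (self.status == STATUS_OK) != (self.temperature_c is not None):
            raise ValueError("temperature must be present exactly when status is ok")


@dataclass(frozen=True)
class PipelineConfig:
    rgb_roi: Rect
    thermal_roi: Rect
    homography: Homography
    scalebar: ScaleBar
    conf_threshold: float = 0.50
    mask_threshold: int = 128
    stride: int = 1

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        missing = [k for k in _REQUIRED_KEYS if k not in doc]
        if not missing and isinstance(doc.get("scalebar"), dict):
            missing += [
                f"scalebar.{k}" for k in _REQUIRED_SCALEBAR_KEYS if k not in doc["scalebar"]
            ]
        if missing:
            raise ConfigError(missing)
        corr = QuadCorrespondence(
            tuple(tuple(p) for p in doc["src_quad"]),
            tuple(tuple(p) for p in doc["dst_quad"]),
        )
        sb = doc["scalebar"]
        return cls(
            rgb_roi=Rect(*doc["rgb_roi"]),
            thermal_roi=Rect(*doc["thermal_roi"]),
            homography=fit_homography(corr),
            scalebar=ScaleBar(
                t_min=float(sb["t_min"]),
                t_max=float(sb["t_max"]),
                y_min=int(sb["y_min"]),
                y_max=int(sb["y_max"]),
                x_med=int(sb["x_med"]),
                bar_width=int(sb.get("bar_width", 10)),
            ),
            conf_threshold=float(doc.get("conf_threshold", 0.50)),
            mask_threshold=int(doc.get("mask_threshold", 128)),
            stride=int(doc.get("stride", 1)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def process_frame(
    pair: FramePair, detector: Detector, cfg: PipelineConfig
) -> list[Measurement]:
    """Measure every confident detection in one frame.

    Returns one Measurement per detection surviving the confidence filter,
    in input order; failed steps are recorded in the status field.
    """
    date = pair.timestamp.strftime("%Y-%m-%d")
    time = pair.timestamp.strftime("%H:%M:%S")
    dets = filter_detections(detect(pair.rgb_panel, detector), cfg.conf_threshold)
    out: list[Measurement] = []
    for det in dets:
        mask = refine_box_mask(pair.rgb_panel, det.box, cfg.mask_threshold)
        try:
            rgb_px = representative_pixel(mask, det.box)
        except NoForegroundError:
            out.append(Measurement(date, time, det.label, None, None, None,
                                   STATUS_NO_FOREGROUND))
            continue
        try:
            thermal_px = map_point(
                cfg.homography, rgb_px, panel_shape=pair.thermal_panel.shape[:2]
            )
        except OutOfPanelError:
            out.append(Measurement(date, time, det.label, rgb_px, None, None,
                                   STATUS_OUT_OF_PANEL))
            continue
        temp = colour_to_temperature(pair.thermal_panel, cfg.scalebar, thermal_px)
        out.append(Measurement(date, time, det.label, rgb_px, thermal_px, temp,
                               STATUS_OK))
    return out


def write_log(measurements: Sequence[Measurement], path: str | Path) -> None:
    """Append measurements to a tab-separated log file.

    One line per measurement: ``date<TAB>time<TAB>label<TAB>value`` where
    value is the temperature to one decimal for ok readings, else the
    status word.  Re-runs append, like a lab notebook.
    """
    lines = []
    for m in measurements:
        value = f"{m.temperature_c:.1f}" if m.status == STATUS_OK else m.status
        lines.append(f"{m.date}\t{m.time}\t{m.label.value}\t{value}")
    with open(path, "a") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_log(path: str | Path) -> list[Measurement]:
    """Parse a log file back into (pixel-less) Measurement records."""
    out = []
    for line in Path(path).read_text().splitlines():
        date, time, label, value = line.split("\t")
        if value in (STATUS_NO_FOREGROUND, STATUS_OUT_OF_PANEL):
            out.append(Measurement(date, time, ClassLabel(label), None, None, None, value))
        else:
            out.append(
                Measurement(date, time, ClassLabel(label), None, None, float(value), STATUS_OK)
            )
    return out
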