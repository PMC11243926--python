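"""Detector contract, confidence filtering, and YOLO-format label I/O.

The pipeline needs bounding boxes for the lizard and six body parts in the
RGB panel, but it does not care where they come from: any object with a
``detect(image) -> list[Detection]`` method is a valid backend.  The
:class:`FixtureDetector` replays scripted boxes (from memory or a YAML
sidecar) and is the backend the test suite and synthetic scenes use; an
external trained model can be wrapped behind the same contract.

Detection runs on the RGB panel only — a model trained on RGB imagery
produces garbage on false-colour thermal frames, and the thermal panel may
not even show the animal when it matches ambient temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import yaml

from .errors import DetectorError
from .frame_io import Rect

__all__ = [
    "ClassLabel",
    "Detection",
    "Detector",
    "FixtureDetector",
    "filter_detections",
    "detect",
    "read_yolo_labels",
    "write_yolo_labels",
    "yolo_to_rect",
    "rect_to_yolo",
]

DEFAULT_CONF_THRESHOLD = 0.50


class ClassLabel(str, Enum):
    """The seven annotated classes: whole animal plus six body parts."""

    LIZARD = "Lizard"
    SNOUT = "Snout"
    HEAD = "Head"
    DORSUM = "Dorsum"
    TAIL = "Tail"
    LEG_L = "Leg_L"
    PALM_L = "Palm_L"

    @classmethod
    def from_index(cls, index: int) -> "ClassLabel":
        return list(cls)[index]

    @property
    def index(self) -> int:
        return list(type(self)).index(self)


@dataclass(frozen=True)
class Detection:
    """One predicted bounding box in RGB-panel coordinates."""

    label: ClassLabel
    box: Rect
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


class Detector(Protocol):
    name: str

    def detect(self, frame: np.ndarray) -> list[Detection]: ...


def filter_detections(
    dets: Sequence[Detection], conf_threshold: float = DEFAULT_CONF_THRESHOLD
) -> list[Detection]:
    """Keep detections with confidence >= threshold, preserving order.

    Ties at the threshold are kept: the cut discards strictly lower scores.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError(f"conf_threshold must be in [0, 1], got {conf_threshold}")
    return [d for d in dets if d.confidence >= conf_threshold]


def _clamp_box(box: Rect, width: int, height: int) -> Rect | None:
    """Clip a box to the frame; None if nothing remains."""
    x1 = max(box.x, 0)
    y1 = max(box.y, 0)
    x2 = min(box.x2, width)
    y2 = min(box.y2, height)
    if x2 <= x1 or y2 <= y1:
        return None
    return Rect(x1, y1, x2 - x1, y2 - y1)


def detect(frame: np.ndarray, detector: Detector) -> list[Detection]:
    """Run a detector backend on the RGB panel and sanitise its output.

    Boxes straddling the frame edge are clamped; boxes entirely outside are
    dropped, so downstream code can rely on every box being inside.
    """
    try:
        raw = detector.detect(frame)
    except Exception as exc:
        raise DetectorError(getattr(detector, "name", repr(detector)), str(exc)) from exc
    h, w = frame.shape[:2]
    out = []
    for det in raw:
        clamped = _clamp_box(det.box, w, h)
        if clamped is not None:
            out.append(Detection(det.label, clamped, det.confidence))
    return out


class FixtureDetector:
    """Deterministic detector replaying scripted boxes.

    ``script`` maps frame index -> list of detections; frames not in the
    script yield no detections.  :meth:`from_yaml` loads a sidecar of the
    form ``{frames: {0: [{class, x, y, w, h, confidence}, ...]}}``.
    """

    name = "fixture"

    def __init__(self, script: dict[int, list[Detection]], frame_counter: bool = True):
        self._script = script
        self._cursor = 0
        self._frame_counter = frame_counter

    @classmethod
    def from_list(cls, dets: Sequence[Detection]) -> "FixtureDetector":
        """Single-frame fixture: every call returns the same boxes."""
        det = cls({0: list(dets)})
        det._frame_counter = False
        return det

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureDetector":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        script: dict[int, list[Detection]] = {}
        for idx, rows in (doc.get("frames") or {}).items():
            script[int(idx)] = [
                Detection(
                    label=ClassLabel(row["class"]),
                    box=Rect(int(row["x"]), int(row["y"]), int(row["w"]), int(row["h"])),
                    confidence=float(row.get("confidence", 1.0)),
                )
                for row in (rows or [])
            ]
        return cls(script)

    def detect(self, frame: np.ndarray) -> list[Detection]:
        if self._frame_counter:
            key = self._cursor
            self._cursor += 1
        else:
            key = 0
        return list(self._script.get(key, []))


def yolo_to_rect(
    cx: float, cy: float, w: float, h: float, img_width: int, img_height: int
) -> Rect:
    """Convert one normalised YOLO box to an absolute pixel Rect.

    Coordinates are rounded half-up; degenerate sizes round up to 1 px.
    """
    pw = w * img_width
    ph = h * img_height
    x = int(np.floor(cx * img_width - pw / 2 + 0.5))
    y = int(np.floor(cy * img_height - ph / 2 + 0.5))
    width = max(1, int(np.floor(pw + 0.5)))
    height = max(1, int(np.floor(ph + 0.5)))
    return Rect(max(0, x), max(0, y), width, height)


def rect_to_yolo(rect: Rect, img_width: int, img_height: int) -> tuple[float, float, float, float]:
    """Inverse of :func:`yolo_to_rect` (up to rounding)."""
    cx = (rect.x + rect.width / 2) / img_width
    cy = (rect.y + rect.height / 2) / img_height
    return cx, cy, rect.width / img_width, rect.height / img_height


def read_yolo_labels(
    path: str | Path, img_width: int, img_height: int, with_confidence: bool = False
) -> list[Detection]:
    """Parse a YOLO label file: ``class cx cy w h [confidence]`` per line."""
    dets = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        label = ClassLabel.from_index(int(parts[0]))
        cx, cy, w, h = map(float, parts[1:5])
        conf = float(parts[5]) if with_confidence and len(parts) > 5 else 1.0
        dets.append(Detection(label, yolo_to_rect(cx, cy, w, h, img_width, img_height), conf))
    return dets


def write_yolo_labels(
    dets: Sequence[Detection],
    path: str | Path,
    img_width: int,
    img_height: int,
    with_confidence: bool = False,
) -> None:
    lines = []
    for det in dets:
        cx, cy, w, h = rect_to_yolo(det.box, img_width, img_height)
        fields = f"{det.label.index} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if with_confidence:
            fields += f" {det.confidence:.4f}"
        lines.append(fields)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
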