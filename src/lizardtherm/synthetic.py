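"""Synthetic paired RGB/thermal scenes with full ground truth.

Emulates the recording rig end to end so every pipeline stage can be
tested without real footage or a trained detector: a dark elliptical
"lizard" (body, head, snout, tail, left leg, left palm) on a light box
floor in the RGB panel; a known temperature field rendered through a
known injective colourmap in the thermal panel, including the embedded
vertical colour scale bar; and a known rectangle-to-rectangle homography
between the panels.

The temperature field is stored at full precision and quantised only when
rendered through the colourmap, so the pipeline's recovery error on a
noiseless scene is analytically bounded by half a bar row-step.

A ``curl_tail`` scene draws the tail as an open arc whose bounding-box
centre falls on background, exercising the nearest-white-pixel fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .detection import ClassLabel, Detection, write_yolo_labels
from .frame_io import FramePair, Rect, extract_roi
from .registration import Homography, QuadCorrespondence, fit_homography
from .thermal_scale import ScaleBar

__all__ = ["SyntheticScene", "make_colourmap", "make_scene", "scene_config", "write_scene"]

PANEL_W = 160
PANEL_H = 120

_LIZARD_COLOUR = np.array([62, 52, 42], dtype=np.uint8)
_FLOOR_COLOUR = np.array([212, 208, 200], dtype=np.uint8)


def make_colourmap(n_steps: int) -> np.ndarray:
    """Injective dark-blue-to-yellow colour ramp, (n, 3) uint8.

    Consecutive colours are at least 4 apart in Euclidean RGB distance so
    that nearest-colour inversion is unambiguous even under +-1 per-channel
    perturbation; this caps ``n_steps`` at 101.
    """
    if n_steps < 2:
        raise ValueError(f"need at least 2 steps, got {n_steps}")
    t = np.arange(n_steps) / (n_steps - 1)
    ramp = np.stack(
        [
            np.floor(255 * t + 0.5),        # red rises
            np.floor(180 * t + 0.5),        # green rises slower
            np.floor(255 * (1 - t) + 0.5),  # blue falls
        ],
        axis=1,
    ).astype(np.uint8)
    gaps = np.sqrt(
        (np.diff(ramp.astype(np.float64), axis=0) ** 2).sum(axis=1)
    )
    if gaps.min() < 4.0:
        raise ValueError(
            f"{n_steps} steps leave consecutive colours only {gaps.min():.2f} apart "
            "(< 4); use a shorter bar"
        )
    return ramp


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered composite frame plus every quantity the pipeline estimates."""

    composite: np.ndarray
    rgb_rect: Rect
    thermal_rect: Rect
    gt_boxes: list[tuple[ClassLabel, Rect]]
    gt_homography: Homography
    gt_scalebar: ScaleBar
    gt_temperature: np.ndarray  # (panel_h, panel_w) float deg C, thermal coords
    colourmap: np.ndarray
    src_quad: tuple
    dst_quad: tuple
    lizard_temp: float
    ambient_temp: float
    seed: int

    def frame_pair(self, frame_index: int = 0, timestamp: datetime | None = None) -> FramePair:
        if timestamp is None:
            timestamp = datetime(2024, 1, 1, 12, 0, 0)
        return FramePair(
            rgb_panel=extract_roi(self.composite, self.rgb_rect),
            thermal_panel=extract_roi(self.composite, self.thermal_rect),
            frame_index=frame_index,
            timestamp=timestamp,
        )

    def gt_detections(self, confidence: float = 1.0) -> list[Detection]:
        return [Detection(lbl, box, confidence) for lbl, box in self.gt_boxes]


def _ellipse_mask(w: int, h: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    ys, xs = np.mgrid[0:h, 0:w]
    return ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0


def _disk_chain(w: int, h: int, points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    mask = np.zeros((h, w), dtype=bool)
    ys, xs = np.mgrid[0:h, 0:w]
    for (px, py), r in zip(points, radii):
        mask |= (xs - px) ** 2 + (ys - py) ** 2 <= r ** 2
    return mask


def _bbox_of(mask: np.ndarray, pad: int, w: int, h: int) -> Rect:
    ys, xs = np.nonzero(mask)
    x1 = max(0, int(xs.min()) - pad)
    y1 = max(0, int(ys.min()) - pad)
    x2 = min(w, int(xs.max()) + 1 + pad)
    y2 = min(h, int(ys.max()) + 1 + pad)
    return Rect(x1, y1, x2 - x1, y2 - y1)


def _part_masks(w: int, h: int, curl_tail: bool) -> dict[ClassLabel, np.ndarray]:
    parts: dict[ClassLabel, np.ndarray] = {}
    parts[ClassLabel.DORSUM] = _ellipse_mask(w, h, 80, 60, 28, 12)
    parts[ClassLabel.HEAD] = _ellipse_mask(w, h, 115, 60, 12, 9)
    parts[ClassLabel.SNOUT] = _ellipse_mask(w, h, 130, 60, 5, 4)
    parts[ClassLabel.LEG_L] = _ellipse_mask(w, h, 66, 78, 6, 10)
    parts[ClassLabel.PALM_L] = _ellipse_mask(w, h, 66, 92, 5, 4)
    if curl_tail:
        # open arc: the tail's bounding-box centre lands on background
        angles = np.linspace(-0.5, 3.6, 40)
        pts = np.stack([40 + 18 * np.cos(angles), 48 - 18 * np.sin(angles)], axis=1)
        radii = np.linspace(3.0, 1.2, 40)
    else:
        pts = np.stack([np.linspace(52, 15, 30), np.full(30, 60.0)], axis=1)
        radii = np.linspace(4.0, 1.2, 30)
    parts[ClassLabel.TAIL] = _disk_chain(w, h, pts, radii)
    return parts


def make_scene(
    t_min: float = 29.3,
    t_max: float = 50.5,
    lizard_temp: float = 36.0,
    ambient_temp: float = 31.0,
    panel_size: tuple[int, int] = (PANEL_W, PANEL_H),
    seed: int = 0,
    curl_tail: bool = False,
    lamp_gradient: float = 0.0,
    dst_rect: tuple[float, float, float, float] | None = None,
) -> SyntheticScene:
    """Render one paired scene with known ground truth.

    ``t_min``/``t_max`` are the scale-bar endpoints; the defaults are the
    worked-example endpoints of the real rig's scale.  ``lamp_gradient``
    adds a linear top-to-bottom temperature ramp of that many deg C to the
    floor (heat-lamp analogue).  ``dst_rect`` overrides the thermal-panel
    rectangle the RGB panel maps onto — place it partly outside the panel
    to provoke out-of-panel measurements.
    """
    if not (t_min <= ambient_temp <= t_max and t_min <= lizard_temp <= t_max):
        raise ValueError("ambient and lizard temperatures must lie within [t_min, t_max]")
    w, h = panel_size
    rng = np.random.default_rng(seed)

    # --- RGB panel ---------------------------------------------------
    parts = _part_masks(w, h, curl_tail)
    lizard_mask = np.zeros((h, w), dtype=bool)
    for m in parts.values():
        lizard_mask |= m

    texture = rng.integers(-6, 7, size=(h, w, 1), dtype=np.int16)
    rgb = np.clip(_FLOOR_COLOUR.astype(np.int16) + texture, 0, 255).astype(np.uint8)
    body_texture = rng.integers(-5, 6, size=(h, w, 1), dtype=np.int16)
    body = np.clip(_LIZARD_COLOUR.astype(np.int16) + body_texture, 0, 255).astype(np.uint8)
    rgb[lizard_mask] = body[lizard_mask]

    gt_boxes = [(ClassLabel.LIZARD, _bbox_of(lizard_mask, 2, w, h))]
    for label in (ClassLabel.SNOUT, ClassLabel.HEAD, ClassLabel.DORSUM,
                  ClassLabel.TAIL, ClassLabel.LEG_L, ClassLabel.PALM_L):
        gt_boxes.append((label, _bbox_of(parts[label], 2, w, h)))

    # --- registration ------------------------------------------------
    bar = ScaleBar(
        t_min=t_min, t_max=t_max, y_min=10, y_max=90, x_med=w - 12, bar_width=10
    )
    if dst_rect is None:
        dst_rect = (4.0, 4.0, float(w - 30), float(h - 5))
    src_rect = (0.0, 0.0, float(w - 1), float(h - 1))
    corr = QuadCorrespondence.from_rects(src_rect, dst_rect)
    hom = fit_homography(corr)

    # --- thermal panel -----------------------------------------------
    ys, xs = np.mgrid[0:h, 0:w]
    temp = np.full((h, w), float(ambient_temp))
    if lamp_gradient:
        temp += lamp_gradient * (1 - ys / (h - 1))
    # lizard footprint: pull every thermal pixel back into the RGB panel
    inv = hom.inverse().m
    pts = np.stack([xs.ravel(), ys.ravel(), np.ones(w * h)])
    back = inv @ pts
    bx = np.floor(back[0] / back[2] + 0.5).astype(np.int64)
    by = np.floor(back[1] / back[2] + 0.5).astype(np.int64)
    inside = (bx >= 0) & (bx < w) & (by >= 0) & (by < h)
    on_lizard = np.zeros(w * h, dtype=bool)
    on_lizard[inside] = lizard_mask[by[inside], bx[inside]]
    temp.ravel()[on_lizard] = lizard_temp
    temp = np.clip(temp, t_min, t_max)

    n_steps = bar.n_rows
    cmap = make_colourmap(n_steps)
    idx = np.floor((temp - t_min) / (t_max - t_min) * (n_steps - 1) + 0.5).astype(np.int64)
    thermal = cmap[idx]

    # scale bar: row y carries the colour of its own interpolated temperature,
    # i.e. colour index (y_max - y)
    x0, x1 = bar.columns()
    for y in range(bar.y_min, bar.y_max + 1):
        thermal[y, x0:x1] = cmap[bar.y_max - y]

    composite = np.concatenate([rgb, thermal], axis=1)
    return SyntheticScene(
        composite=composite,
        rgb_rect=Rect(0, 0, w, h),
        thermal_rect=Rect(w, 0, w, h),
        gt_boxes=gt_boxes,
        gt_homography=hom,
        gt_scalebar=bar,
        gt_temperature=temp,
        colourmap=cmap,
        src_quad=corr.src,
        dst_quad=corr.dst,
        lizard_temp=float(lizard_temp),
        ambient_temp=float(ambient_temp),
        seed=seed,
    )


def scene_config(scene: SyntheticScene) -> dict:
    """Pipeline config dict matching the scene's ground truth."""
    bar = scene.gt_scalebar
    return {
        "rgb_roi": [scene.rgb_rect.x, scene.rgb_rect.y, scene.rgb_rect.width, scene.rgb_rect.height],
        "thermal_roi": [scene.thermal_rect.x, scene.thermal_rect.y,
                        scene.thermal_rect.width, scene.thermal_rect.height],
        "src_quad": [list(p) for p in scene.src_quad],
        "dst_quad": [list(p) for p in scene.dst_quad],
        "scalebar": {
            "t_min": bar.t_min, "t_max": bar.t_max,
            "y_min": bar.y_min, "y_max": bar.y_max,
            "x_med": bar.x_med, "bar_width": bar.bar_width,
        },
        "conf_threshold": 0.50,
        "mask_threshold": 128,
        "stride": 1,
    }


def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write composite PNG, YOLO ground-truth labels, and a YAML sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png = out / "composite.png"
    iio.imwrite(png, scene.composite)
    labels = out / "labels.txt"
    write_yolo_labels(
        scene.gt_detections(), labels, scene.rgb_rect.width, scene.rgb_rect.height
    )
    sidecar = out / "ground_truth.yaml"
    doc = {
        "seed": scene.seed,
        "lizard_temp": scene.lizard_temp,
        "ambient_temp": scene.ambient_temp,
        "homography": [[float(v) for v in row] for row in scene.gt_homography.m],
        "config": scene_config(scene),
    }
    sidecar.write_text(yaml.safe_dump(doc, sort_keys=False))
    return {"composite": png, "labels": labels, "sidecar": sidecar}
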