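# Methods

## Problem setting and model

A lizard in a laboratory box is filmed simultaneously by an RGB camera and
a thermal camera; both outputs are screen-recorded side by side into one
composite frame. The package turns each composite frame into per-body-part
temperature readings. The measurement model has four independent parts:

**Panel geometry.** Panels are axis-aligned rectangles inside the
composite, supplied by the user per recording setup (the split line is
not auto-detected). Coordinates are 0-based, `(x = column, y = row)`,
y increasing downward, half-open extents. This convention is applied
uniformly — ROI slicing, masks, box centres, homography, bar rows.

**Foreground model.** The animal is assumed darker than the floor. Inside
each bounding box, grayscale luma (0.299 R + 0.587 G + 0.114 B, rounded)
at or below a user threshold (default 128) is foreground. The threshold is
deliberately manual — lighting in the rig is controlled, and a fixed
threshold keeps the decision auditable; no Otsu-style auto method is
offered. The representative pixel is the integer box centre (floor
division for even sides) when it is foreground, else the foreground pixel
nearest in Euclidean distance, searched **within the box only**:
foreground outside the box belongs to other detections. Ties break by
row-major order (smallest y, then x), making the pixel deterministic.
Boxes with no foreground at all yield a `no_foreground` status rather
than a reading.

**Registration.** The floor is approximately planar, so a 3×3 projective
homography fitted from exactly four point pairs (the corners of the box
visible in both panels, in a fixed corner order) maps RGB pixels to
thermal pixels. The fit solves the standard 8-unknown linear system with
`m[2,2] = 1`; corner reprojection error is far below 1e-6 px away from
degeneracy, and quads with a collinear triple are rejected. Mapped
coordinates are rounded by `floor(v + 0.5)`. Negative or out-of-panel
results are **not** clamped — clamping would silently read a wrong
temperature — they produce an `out_of_panel` status.

**Colour-scale calibration.** The thermal panel embeds a vertical colour
bar whose ends are annotated with the frame's extreme temperatures; the
user supplies `t_min`, `t_max`, the bar's top and bottom rows
(`y_min` hot, `y_max` cold) and centre column, exactly as they would read
them off the image (no OCR). Row → temperature is linear interpolation.
Colour → row is nearest-colour matching in Euclidean RGB distance against
the bar sampled one mean colour per row across its (nominally 10 px)
width; the averaging suppresses screen-capture compression noise. Ties
prefer the smaller row (hotter). The bar is the only calibration
available from a screen recording, so a reading's resolution is one bar
row: `step = (t_max − t_min)/(y_max − y_min)` °C. The colour-matching
rule is the one genuinely open design point (the interpolation formula
alone does not define it); nearest-colour with deterministic tie-break is
the minimal completion. Per-frame bar rescaling in videos is not
modelled: the scale is fixed per run, with per-file overrides.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `conf_threshold` | 0.50 | discard detections below this confidence (ties kept) |
| `iou_threshold` | 0.50 | minimum overlap for a detection to count as correct |
| `mask_threshold` | 128 | grayscale cut between animal and floor, 0–255 |
| `bar_width` | 10 px | colour-bar width averaged when sampling |
| `stride` | 1 | process every frame; `legacy_stride(fps)` reproduces the manual 20 s cadence |

## Detection contract

The detector is a one-method contract (`image → detections`) so the
pipeline does not depend on trained weights. The shipped backend is a
deterministic fixture replaying scripted boxes (YAML sidecar or a
synthetic scene's ground truth); a trained model can be wrapped behind the
same contract. Multiple detections of one class are processed
independently — the pipeline does not enforce one box per class.

## Evaluation metrics

Greedy confidence-ordered matching per class (each prediction claims the
unmatched ground truth of highest IoU ≥ threshold) is the YOLO-ecosystem
convention; it is a 1/2-approximation to the optimal assignment, and the
test suite bounds it against an exhaustive-assignment oracle on small
instances. AP uses all-point interpolation (the monotone precision
envelope integrated over recall), not the older 11-point variant;
mAP@0.5:0.95 averages over IoU thresholds 0.50–0.95 in steps of 0.05.
Degenerate zero-denominator precision/recall return 0 with a flag.

## Dataset accounting

The split dialect is floor(train), floor(val), remainder(test) — the only
rounding consistent with partitioning 4306 frames 70/20/10 into
3014/861/431. Augmented copies are added alongside originals:
`n_full + copies × n_train` (two copies per training frame takes 4306 to
10,334). Augmentation jitters saturation, brightness and exposure within
±10%, blurs up to 1 px, and flips at most 1% of pixels to salt/pepper;
"exposure" is implemented as a gamma-style adjustment to keep it distinct
from the linear brightness gain, since the two are named separately but
not defined. All augmentation is deterministic given a seed.

## Synthetic scenes

`make_scene` renders a 160×120 px panel pair: a dark (luma ≈ 54 ± 5)
elliptical lizard with six part sub-shapes on a light (luma ≈ 208 ± 6)
textured floor; a full-precision temperature field (ambient floor,
optional linear lamp gradient, lizard at its own temperature) rendered
through an injective 81-step colourmap; an 81-row colour bar; and a
rectangle-to-rectangle homography between panels. Default temperatures —
bar 29.3–50.5 °C, floor 31 °C, lizard 36 °C — sit in the rig's working
range. Quantisation happens only at rendering, so the pipeline's recovery
error on a noiseless scene is analytically ≤ half a bar step. A
`curl_tail` flag draws the tail as an open arc whose bounding-box centre
falls on background, forcing the nearest-white-pixel branch.

The colourmap guarantees ≥ 4 Euclidean distance between consecutive
colours after 8-bit rounding, so nearest-colour inversion is exact and
survives ±1 per-channel perturbation; this caps the bar at ~101 rows
(81 used, worst-case gap 4.69).

What the scenes do **not** model: sensor noise, compression artefacts,
the thermal camera's ±2 °C radiometric accuracy (a hardware property
outside this software's scope), motion blur, non-planar geometry, and
non-uniform animal colouring. Passing tests therefore demonstrate the
correctness of the algorithmic chain, not field accuracy on real footage.

## Numerical choices and edge cases

- All rounding of coordinates and 8-bit channels is `floor(v + 0.5)`
  (half-up), matching the mapping equations; Python's banker's rounding is
  never used.
- Homography round-trip: forward rounding costs ≤ 0.5 px in the
  destination panel, which the inverse magnifies by the reciprocal axis
  scale. The ≤ 1 px round-trip property therefore holds for axis scales
  ≥ 0.5; tests and property suites draw scales in [0.6, 2], matching the
  similarly sized camera panels.
- Boxes straddling the frame edge are clamped on detector output; boxes
  fully outside are dropped there, so downstream stages assume validity.
- Log lines always equal surviving detections in number — failures are
  logged as statuses, never dropped.
- Timestamps are injectable (tests pass a fixed clock); real runs use the
  frame timestamp derived from file mtime and frame rate.

## Problem sizes used in checks

Property suites run 1000 random rectangle correspondences (corner
reproduction and round-trip), 500 random 15×15 masks against a
brute-force nearest-white scan, 200 random PR curves against fine-grid
integration, and 50 seeded noiseless scenes end-to-end; these sizes give
dense coverage of the branch structure while keeping the whole suite
interactive.

## Known limitations

- No radiometric conversion, emissivity or reflected-temperature
  handling; readings are bounded by the colour bar's row resolution.
- Exactly four calibration points; no least-squares multi-point fit or
  lens-distortion model.
- Fixed colour scale per run; a video whose bar endpoints change
  mid-stream needs per-segment configs.
- Video decoding relies on the codecs available to imageio; multi-frame
  GIF/TIFF work everywhere, MP4/AVI wherever an ffmpeg plugin is present.
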