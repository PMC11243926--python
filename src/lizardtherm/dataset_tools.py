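"""Dataset bookkeeping: train/val/test split accounting and augmentation.

The detector's training corpus was 4306 frames pulled from ~10 ten-minute
recordings, split 70/20/10 into train/val/test and expanded by photometric
augmentation of the training images only (saturation, brightness and
exposure jitter within +-10%, blur up to 1 px, salt-and-pepper noise on up
to 1% of pixels).  These helpers reproduce that arithmetic exactly and
provide a deterministic augmenter for building comparable corpora.

Rounding dialect: train and val counts are floored, test takes the
remainder — the only dialect consistent with the published 3014/861/431
partition of 4306.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image, ImageEnhance, ImageFilter
from scipy import ndimage

__all__ = [
    "SplitSpec",
    "AugmentParams",
    "split_counts",
    "assign_split",
    "augmented_total",
    "augment_image",
    "resize_image",
]

DEFAULT_RATIOS = (0.7, 0.2, 0.1)
YOLO_INPUT_SIZE = 640


def _check_ratios(ratios: Sequence[float]) -> None:
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError(f"ratios must be three non-negative numbers, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got sum {sum(ratios)}")


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float]
    n_total: int

    def __post_init__(self):
        _check_ratios(self.ratios)
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")

    def counts(self) -> tuple[int, int, int]:
        return split_counts(self.n_total, self.ratios)


@dataclass(frozen=True)
class AugmentParams:
    """Photometric jitter bounds; defaults are the training-corpus settings."""

    saturation_jitter: float = 0.10
    brightness_jitter: float = 0.10
    exposure_jitter: float = 0.10
    blur_px: float = 1.0
    noise_frac: float = 0.01
    copies_per_image: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("saturation_jitter", "brightness_jitter", "exposure_jitter",
                     "blur_px", "noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


def split_counts(
    n_total: int, ratios: Sequence[float] = DEFAULT_RATIOS
) -> tuple[int, int, int]:
    """Partition sizes (train, val, test): floor, floor, remainder."""
    _check_ratios(ratios)
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    n_train = int(n_total * ratios[0])
    n_val = int(n_total * ratios[1])
    return n_train, n_val, n_total - n_train - n_val


def assign_split(
    ids: Sequence, ratios: Sequence[float] = DEFAULT_RATIOS, seed: int = 0
) -> tuple[list, list, list]:
    """Deterministic shuffled partition of unique ids into the three sets."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    rng = random.Random(seed)
    shuffled = ids[:]
    rng.shuffle(shuffled)
    n_train, n_val, _ = split_counts(len(ids), ratios)
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def augmented_total(n_full: int, n_train: int, copies_per_image: int = 2) -> int:
    """Corpus size after adding augmented copies of each training image.

    Augmented variants are added alongside the originals, so the corpus
    grows by copies x train-set size (4306 + 2 x 3014 = 10,334).
    """
    if n_train > n_full:
        raise ValueError("n_train cannot exceed n_full")
    if copies_per_image < 0:
        raise ValueError("copies_per_image must be >= 0")
    return n_full + n_train * copies_per_image


def augment_image(img: np.ndarray, params: AugmentParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """One photometrically jittered copy of an 8-bit colour image.

    Saturation and brightness are multiplicative factors sampled uniformly
    in 1 +- jitter; exposure is a gamma-style adjustment (distinct from the
    brightness gain); blur is Gaussian with a radius sampled up to
    ``blur_px``; noise flips up to ``noise_frac`` of pixels to salt or
    pepper.  With all bounds zero the image is returned bit-identical.
    Deterministic for a fixed rng state.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = img

    sat = 1.0 + rng.uniform(-params.saturation_jitter, params.saturation_jitter)
    bri = 1.0 + rng.uniform(-params.brightness_jitter, params.brightness_jitter)
    expo = 1.0 + rng.uniform(-params.exposure_jitter, params.exposure_jitter)
    radius = rng.uniform(0.0, params.blur_px) if params.blur_px > 0 else 0.0

    if sat != 1.0 or bri != 1.0:
        pil = Image.fromarray(out)
        if sat != 1.0:
            pil = ImageEnhance.Color(pil).enhance(sat)
        if bri != 1.0:
            pil = ImageEnhance.Brightness(pil).enhance(bri)
        out = np.asarray(pil)
    if expo != 1.0:
        # gamma-style exposure: out = 255 * (in/255)^(1/expo)
        lut = np.floor(255.0 * (np.arange(256) / 255.0) ** (1.0 / expo) + 0.5).astype(np.uint8)
        out = lut[out]
    if radius > 0:
        out = np.stack(
            [ndimage.gaussian_filter(out[..., c].astype(np.float64), sigma=radius)
             for c in range(out.shape[2])],
            axis=-1,
        )
        out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    if params.noise_frac > 0:
        h, w = out.shape[:2]
        n_noisy = int(rng.integers(0, max(1, int(params.noise_frac * h * w)) + 1))
        if n_noisy:
            out = out.copy()
            ys = rng.integers(0, h, n_noisy)
            xs = rng.integers(0, w, n_noisy)
            vals = rng.choice([0, 255], n_noisy)
            out[ys, xs] = vals[:, None]
    return out


def resize_image(img: np.ndarray, size: int = YOLO_INPUT_SIZE) -> np.ndarray:
    """Resize to the detector's square input size (bilinear)."""
    pil = Image.fromarray(img).resize((size, size), Image.BILINEAR)
    return np.asarray(pil)
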