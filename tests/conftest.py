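from datetime import datetime

import numpy as np
import pytest

from lizardtherm import (
    FixtureDetector,
    PipelineConfig,
    make_scene,
    scene_config,
)


@pytest.fixture(scope="session")
def scene():
    """One noiseless straight-tail scene shared across read-only tests."""
    return make_scene(seed=11)


@pytest.fixture(scope="session")
def curl_scene():
    """Scene whose tail box centre lands on background."""
    return make_scene(seed=12, curl_tail=True)


@pytest.fixture
def pipeline_parts(scene):
    cfg = PipelineConfig.from_dict(scene_config(scene))
    detector = FixtureDetector.from_list(scene.gt_detections())
    return scene.frame_pair(timestamp=datetime(2024, 3, 1, 9, 30, 0)), detector, cfg


def checkerboard(h, w, dark=40, light=220):
    """Deterministic two-tone test image."""
    img = np.zeros((h, w, 3), dtype=np.uint8)
    ys, xs = np.mgrid[0:h, 0:w]
    img[...] = np.where(((ys + xs) % 2 == 0)[..., None], dark, light)
    return img
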