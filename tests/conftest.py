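import numpy as np
import pytest

from beecount.geometry import EntranceGeometry, Point2D
from beecount.simulate import ScenarioConfig
from beecount.tracker import BBox, Detection, TrackObservation


@pytest.fixture
def entrance() -> EntranceGeometry:
    """Horizontal entrance segment near the bottom image border."""
    return EntranceGeometry(
        Point2D(300.0, 470.0), Point2D(340.0, 470.0), 30.0, 640.0, 480.0
    )


def clean_config(seed: int, **kwargs) -> ScenarioConfig:
    """Scenario with every corruption source switched off."""
    defaults = dict(
        motion_jitter_sigma=0.0,
        detection_noise_sigma=0.0,
        p_miss=0.0,
        false_positive_rate=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)


def gt_counts(scene) -> tuple[int, int]:
    n_in = sum(1 for e in scene.ground_truth.events if e.direction.value == "IN")
    n_out = sum(1 for e in scene.ground_truth.events if e.direction.value == "OUT")
    return n_in, n_out


def linear_scene(n_obj: int, n_frames: int, speed: float = 2.0):
    """Disjoint objects moving at constant velocity; gt and detections."""
    gt: list[TrackObservation] = []
    dets: list[Detection] = []
    for k in range(n_obj):
        y = 40.0 * k + 20.0
        for f in range(1, n_frames + 1):
            b = BBox(5.0 + speed * f, y, 20.0, 12.0)
            gt.append(TrackObservation(f, k + 1, b))
            dets.append(Detection(f, b))
    return gt, dets
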