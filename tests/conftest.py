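import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecti.afm_io import BoundingBox, Detection, DetectionSet

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def make_detection_set(boxes, scores=None, image_w=512, image_h=512,
                       source="classical") -> DetectionSet:
    """Build a DetectionSet from an iterable of (x0, y0, x1, y1) tuples."""
    dets = []
    for i, b in enumerate(boxes):
        score = None if scores is None else float(scores[i])
        dets.append(Detection(box=BoundingBox(*map(float, b)), score=score))
    return DetectionSet(detections=dets, image_w=image_w, image_h=image_h,
                        source=source)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
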