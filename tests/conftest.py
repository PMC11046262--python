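import numpy as np
import pytest

from engagetrack.geometry import (MarkerObservation, Point2D,
                                  RegionOfInterest, WallSpec)
from engagetrack.scoring import ClassifierConfig


@pytest.fixture
def right_wall() -> WallSpec:
    """Vertical module wall at x=100, chamber interior to its left."""
    return WallSpec(p0=Point2D(100, 0), p1=Point2D(100, 100),
                    interior_hint=Point2D(50, 50))


@pytest.fixture
def unit_square_obs():
    """Factory: axis-aligned square marker observation at given offset."""
    def make(dx: float = 0.0, dy: float = 0.0, side: float = 10.0,
             camera_id: str = "cam1", marker_id: int = 0,
             timestamp: float = 0.0, frame_index: int = 0):
        return MarkerObservation(
            camera_id=camera_id, frame_index=frame_index,
            timestamp=timestamp, marker_id=marker_id,
            corners=(Point2D(dx, dy), Point2D(dx + side, dy),
                     Point2D(dx + side, dy + side), Point2D(dx, dy + side)))
    return make


@pytest.fixture
def simple_classifier(right_wall) -> ClassifierConfig:
    """One camera, square ROI x in [40, 100], wall on the right edge.

    front_edge=1 so an axis-aligned square marker (corners listed from its
    top-left) heads rightward, squarely at the wall (yaw 90 deg).
    """
    roi = RegionOfInterest(camera_id="cam1", vertices=(
        Point2D(40, 0), Point2D(100, 0), Point2D(100, 100), Point2D(40, 100)))
    return ClassifierConfig(rois={"cam1": (roi,)}, walls={"cam1": right_wall},
                            front_edge=1, target_marker_id=0)
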