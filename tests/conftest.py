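import numpy as np
import pytest

from gaitpix.landmark_io import Landmark, LandmarkFrame, LandmarkSequence
from gaitpix.synthetic_gait import (
    SimulationConfig,
    simulate_gait,
    simulate_static_pose,
)


@pytest.fixture(scope="session")
def short_walk():
    """Noiseless treadmill walk long enough for >= 2 full cycles per leg."""
    return simulate_gait(SimulationConfig(n_steps=6, seed=0))


@pytest.fixture(scope="session")
def walk_30():
    """Noiseless 30-step treadmill walk (pedometer protocol size)."""
    return simulate_gait(SimulationConfig(n_steps=30, seed=0))


@pytest.fixture(scope="session")
def static_capture():
    return simulate_static_pose(SimulationConfig(seed=0))


def make_track_sequence(points, name="knee", side="left", fps=25.0, visibility=1.0):
    """Sequence holding a single landmark track; None entries are dropped frames."""
    frames = []
    for i, pt in enumerate(points):
        frame = LandmarkFrame(frame_index=i, timestamp=i / fps)
        if pt is not None:
            frame.add(
                Landmark(name=name, side=side, x=float(pt[0]), y=float(pt[1]),
                         visibility=visibility)
            )
        frames.append(frame)
    return LandmarkSequence(frames=frames, nominal_rate=fps)
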