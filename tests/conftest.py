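import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from larvatrack.frames_io import FrameGrid
from larvatrack.pipeline import TrackConfig, track_recording
from larvatrack.synthetic import SceneSpec, generate_scene

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_frame(pixels: np.ndarray, index: int = 0, rate_hz: float = 1.0) -> FrameGrid:
    return FrameGrid(pixels=np.asarray(pixels, dtype=float), frame_index=index,
                     time_s=index / rate_hz)


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    """One dish of four larvae for ten seconds; small frame, default noise."""
    return SceneSpec(
        n_dishes=1, larvae_per_dish=4, duration_s=10, seed=7,
        frame_width=320, frame_height=200,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec)


@pytest.fixture(scope="session")
def tracked_small(small_spec, small_scene):
    recording, truth = small_scene
    result = track_recording(recording, small_spec.effective_layout(), TrackConfig())
    return result, truth
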