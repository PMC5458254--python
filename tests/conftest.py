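import numpy as np
import pytest

from oemri import DynamicSeries, StageTiming, default_phantom_spec, generate_phantom


@pytest.fixture(scope="session")
def timing() -> StageTiming:
    return StageTiming.from_durations((300.0, 300.0, 300.0))


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default concentric phantom without noise, plus its ground truth."""
    spec = default_phantom_spec(seed=0, noise_sigma=0.0)
    series, truth = generate_phantom(spec)
    return spec, series, truth


def make_series(frames, frame_interval=75.0, pixel_size=(1.0, 1.0)):
    """Small hand-built series; default spacing puts 4 frames per 300-s stage."""
    data = np.asarray(frames, dtype=float)
    times = np.arange(data.shape[0]) * frame_interval
    return DynamicSeries(data=data, times=times, pixel_size=pixel_size)


@pytest.fixture
def constant_series():
    """12-frame constant series at SI 100 on a 4x4 grid (4 frames/stage)."""
    return make_series(np.full((12, 4, 4), 100.0))
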