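import numpy as np
import pytest

from qpli.synth import SensorParams, generate_scene, render_mosaic, uniform_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def aligned_scene():
    """Small aligned phantom with a quarter-wave retarder at every pixel."""
    return generate_scene("aligned", shape=(64, 64), seed=0, retardance_rad=np.pi / 2)


@pytest.fixture
def noise_free_mosaic(aligned_scene):
    return render_mosaic(aligned_scene, SensorParams(), noise=False)


@pytest.fixture
def quarter_wave_uniform():
    return uniform_scene(shape=(32, 32), fiber_axis_deg=20.0, retardance_rad=np.pi / 2)
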