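import numpy as np
import pytest

from gaitsel import synth
from gaitsel.windowing import RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gait_recording():
    """Default ~60 s synthetic 3-channel recording at 100 Hz."""
    return synth.simulate_gait_recording(synth.GaitSimConfig(seed=11))


@pytest.fixture
def short_recording():
    """10 s, 4-mode recording for cheap windowing/feature tests."""
    config = synth.GaitSimConfig(
        seed=21,
        schedule=[("ST", 2.0), ("SW", 3.0), ("NW", 3.0), ("FW", 2.0)],
    )
    return synth.simulate_gait_recording(config)


@pytest.fixture
def planted_table():
    """240 x 30 binary-class table; columns 0-4 informative at effect 1.2."""
    return synth.generate_planted_table(
        synth.PlantedTableConfig(
            m=240, n=30, informative=(0, 1, 2, 3, 4), effect_size=1.2, seed=42
        )
    )


@pytest.fixture
def separable_table():
    """Strongly separated 2-class table (CV error 0 with a linear model)."""
    return synth.generate_planted_table(
        synth.PlantedTableConfig(
            m=120, n=6, informative=(0, 1, 2), effect_size=8.0, seed=7
        )
    )


@pytest.fixture
def tiny_recording():
    """Hand-built recording: 1 s at 100 Hz, 2 channels."""
    t = np.arange(100) / 100.0
    samples = np.column_stack([np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)])
    labels = np.array(["A"] * 50 + ["B"] * 50)
    return RawRecording(samples=samples, fs=100.0, labels=labels)
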