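import numpy as np
import pytest

from stresscare.recording_io import Channel, Recording
from stresscare.synth import SynthConfig


@pytest.fixture
def tiny_recording() -> Recording:
    """120 s wrist recording: 60 s baseline then 60 s stress, simple signals."""
    rng = np.random.default_rng(42)
    dur = 120
    labels = np.array([0] * (60 * 4) + [1] * (60 * 4))
    t64 = np.arange(dur * 64) / 64.0
    channels = [
        Channel("BVP", "wrist", 64.0, np.sin(2 * np.pi * 1.2 * t64)),
        Channel("EDA", "wrist", 4.0, 2.0 + 0.01 * rng.standard_normal(dur * 4)),
        Channel("TEMP", "wrist", 4.0, 33.0 + 0.01 * rng.standard_normal(dur * 4)),
        Channel("sweat", "wrist", 4.0, 1.0 + 0.01 * rng.standard_normal(dur * 4)),
        Channel("ACC_x", "wrist", 32.0, 0.02 * rng.standard_normal(dur * 32)),
        Channel("ACC_y", "wrist", 32.0, 0.02 * rng.standard_normal(dur * 32)),
        Channel("ACC_z", "wrist", 32.0, 1.0 + 0.02 * rng.standard_normal(dur * 32)),
    ]
    return Recording("tiny", channels, labels, 4.0)


@pytest.fixture
def short_synth_config() -> SynthConfig:
    """A fast 3-subject cohort: 300 s of baseline/stress per subject."""
    return SynthConfig(
        n_subjects=3,
        schedule=(("baseline", 150.0), ("stress", 150.0)),
        master_seed=0,
    )
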