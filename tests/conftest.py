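import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from btk.synthetic_data import GaitParams, generate_gait_pose


@pytest.fixture(scope="session")
def clean_gait():
    """Noise-free gait recording with ground truth (shared; read-only)."""
    params = GaitParams(noise_sd=0.0, dropout_rate=0.0, seed=7)
    track, truth = generate_gait_pose(params)
    return params, track, truth


@pytest.fixture(scope="session")
def noisy_gait():
    """Default-noise gait recording with ground truth (shared; read-only)."""
    params = GaitParams(seed=11)
    track, truth = generate_gait_pose(params)
    return params, track, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
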