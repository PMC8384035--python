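import numpy as np
import pytest

from myogait import SimConfig, generate_trial
from myogait.features import build_feature_frame
from myogait.io import align

SELECTED = ["RF", "TA", "ST", "GM", "GL"]


@pytest.fixture(scope="session")
def short_trial():
    """20 s synthetic walking trial, fixed seed."""
    return generate_trial(SimConfig(duration_s=20.0, seed=7))


@pytest.fixture(scope="session")
def aligned_short(short_trial):
    return align(short_trial)


@pytest.fixture(scope="session")
def frame_short(aligned_short):
    """Feature frame over the five-muscle subset of the short trial."""
    return build_feature_frame(aligned_short, channels=SELECTED)


@pytest.fixture(scope="session")
def medium_frame():
    """~2 min trial windowed over the five-muscle subset (model training)."""
    trial = generate_trial(SimConfig(duration_s=120.0, seed=11))
    return build_feature_frame(align(trial), channels=SELECTED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
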