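import numpy as np
import pytest

from compoundv.flock_io import SPECIES, compute_kinematics, wingbeat_sample_frames
from compoundv.synthetic import SyntheticTruth, generate_compound_v


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def godwit():
    return SPECIES["godwit"]


@pytest.fixture(scope="session")
def small_flock():
    """A 120-bird compound-V godwit flock with tight alignment noise,
    plus its kinematics and one-wingbeat sample frames (session-scoped:
    read-only in tests)."""
    truth = SyntheticTruth(lateral_sd=0.15, trailing_sd=0.15, elevation_sd=0.15, seed=7)
    flock, truth = generate_compound_v(120, "godwit", truth, duration_s=2.0)
    kin = compute_kinematics(flock)
    sample = wingbeat_sample_frames(flock)
    return flock, truth, kin, sample
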