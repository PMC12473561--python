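import numpy as np
import pytest

import treadgait as tg
from treadgait.joints import JOINT_INDEX, N_JOINTS
from treadgait.skeleton_io import SkeletonSequence


@pytest.fixture(scope="session")
def clean_walk():
    """60 s noiseless treadmill walk with ground truth."""
    return tg.simulate(tg.SimConfig(duration=60.0, noise_sd=0.0, seed=101))


@pytest.fixture(scope="session")
def clean_analysis(clean_walk):
    seq, _ = clean_walk
    return tg.analyze_sequence(seq)


@pytest.fixture(scope="session")
def noisy_walk():
    """60 s walk at the default 2 mm sensor noise."""
    return tg.simulate(tg.SimConfig(duration=60.0, noise_sd=2.0, seed=202))


@pytest.fixture(scope="session")
def default_table():
    return tg.default_table()


def make_static_seq(n: int = 60, fs: float = 15.0, base: float = 500.0) -> SkeletonSequence:
    """All-valid sequence with every joint parked at a distinct static point;
    tests override individual joint tracks."""
    t = np.arange(n) / fs
    pos = np.zeros((n, N_JOINTS, 3))
    for name, ji in JOINT_INDEX.items():
        pos[:, ji, :] = [base + 10.0 * ji, base - 10.0 * ji, 100.0 + 40.0 * ji]
    return SkeletonSequence(t, pos, np.ones((n, N_JOINTS), dtype=bool), sample_rate_hz=fs)
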