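import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from axialkin import (JointProgram, JointRamp, build_preset, simulate_strike)


@pytest.fixture
def rng():
    return np.random.default_rng(20210825)


@pytest.fixture(scope="session")
def mini_trout():
    """Three-vertebra trout chain for fast unit tests (no whole-body drift)."""
    return build_preset("trout", n_vertebrae=3, whole_body_motion=False)


@pytest.fixture(scope="session")
def frogfish_chain():
    return build_preset("frogfish")


@pytest.fixture
def static_strike(mini_trout):
    """Zero program, zero noise: nothing moves."""
    return simulate_strike(mini_trout, JointProgram({}), duration_s=0.02)


def single_joint_strike(chain, joint, amp_deg, duration_s=0.06,
                        onset_s=0.01, rise_s=0.03, noise=None):
    prog = JointProgram({joint: JointRamp(amp_deg, onset_s=onset_s,
                                          rise_s=rise_s)})
    return simulate_strike(chain, prog, duration_s=duration_s, noise=noise)
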