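import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/helpers.py importable

import arousalkit as ak


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def a1_recording():
    """300 s of pure relaxed wakefulness (A1) EEG with its trajectory."""
    rng = np.random.default_rng(101)
    traj = ak.simulate_stage_sequence(
        ak.TrajectoryParams(decline_rate=0.0, recovery_rate=0.0, duration_s=300), rng
    )
    rec = ak.synthesize_eeg(traj, None, rng)
    return traj, rec


@pytest.fixture(scope="session")
def declining_recording():
    """A1 for the first 3 min, then drowsiness (B2/3) to the end."""
    from helpers import seq_from_spans

    from arousalkit.synthetic import SimulatedTrajectory

    rng = np.random.default_rng(202)
    seq = seq_from_spans([("A1", 180), ("B2/3", 240)])
    traj = SimulatedTrajectory(seq, None, [], [])
    rec = ak.synthesize_eeg(traj, None, rng)
    return seq, rec
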