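import numpy as np
import pytest

from gripstretch.schedule import CatchProbe, TrialSpec
from gripstretch.synth import ControllerParams, generate_trial_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_controller():
    return ControllerParams(noise_sd=0.0)


@pytest.fixture
def gain100_trial():
    """Standard-field test trial at the largest stretch gain, catch at probe 7."""
    return TrialSpec(
        experiment="exp1",
        group="none",
        session=1,
        phase="test",
        trial_index=0,
        comparison_stiffness=85.0,
        gain=100.0,
        catch_probe=CatchProbe.PROBE7,
    )


@pytest.fixture
def noiseless_trajectory(gain100_trial, noiseless_controller):
    """Noiseless standard-field trajectory of one 8-probe trial at 500 Hz."""
    rng = np.random.default_rng(0)
    traj = generate_trial_trajectory(
        gain100_trial, noiseless_controller, rng, fs=500.0, fields=("standard",)
    )
    return traj
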