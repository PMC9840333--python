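import numpy as np
import pytest

from neurochirp import synth

FRONTAL = ("F3", "F1", "Fz", "F2", "F4")


@pytest.fixture(scope="session")
def stimulus():
    return synth.make_chirp_stimulus()


@pytest.fixture(scope="session")
def small_schedule():
    return synth.make_trial_schedule(n_trials=12, seed=7)


@pytest.fixture(scope="session")
def locked_session(stimulus, small_schedule):
    """Strongly phase-locked, low-noise session on the frontal montage."""
    params = synth.SimParams(
        channels=FRONTAL,
        phase_locking_kappa=1e9,
        entrain_gain=40.0,
        onset_theta_gain=20.0,
        noise_scale=2.0,
        seed=21,
    )
    return synth.simulate_eeg_session(params, small_schedule, stimulus)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
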