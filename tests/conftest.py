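import numpy as np
import pytest

import reachbci as rb
from reachbci.paradigm import SynthConfig


@pytest.fixture(scope="session")
def montage():
    return rb.default_montage()


@pytest.fixture(scope="session")
def small_session():
    """A reduced synthetic session shared by pipeline-level tests:
    2 movlook + 2 onlylook calibration runs, 1 eyeblock pair, 1 online run."""
    schedule = rb.build_schedule(11, n_movlook_runs=2, n_onlylook_runs=2,
                                 n_online_runs=1)
    runs = rb.simulate_session(SynthConfig(), schedule, seed=11)
    return schedule, runs


@pytest.fixture(scope="session")
def small_calibration(small_session):
    schedule, runs = small_session
    return rb.assemble_calibration(runs, schedule, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
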