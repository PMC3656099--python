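import numpy as np
import pytest
from hypothesis import settings

from strandmig import synthetic as syn
from strandmig.registry import build_default_registry

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def duplex():
    return syn.build_aform_duplex("GUUAUGCGCAU")


@pytest.fixture(scope="session")
def mig_schedule():
    # 200 frames, event at 80; closing pair frays after 92 frames (18.2 ns)
    return syn.default_schedule(200, 80)


@pytest.fixture(scope="session")
def noiseless(registry, mig_schedule):
    traj, sched = syn.generate_switch_trajectory(registry, mig_schedule, 0.0, 1)
    return traj, sched


@pytest.fixture(scope="session")
def noisy(registry, mig_schedule):
    traj, sched = syn.generate_switch_trajectory(registry, mig_schedule, 0.1, 3)
    return traj, sched


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
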