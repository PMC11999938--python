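import numpy as np
import pytest

from emgforce import sim
from emgforce.preprocess import PreprocessConfig

# scaled-down study conditions shared across tests: 1 kHz sampling, the
# 3 s ramp + 3 s plateau effort, 64-channel child grid
FS = 1000.0


@pytest.fixture(scope="session")
def ramp_force():
    return sim.generate_force_profile(
        "increasing_plateau", 6.0, FS,
        {"ramp_s": 3.0, "plateau_s": 3.0, "amplitude": 0.6})


@pytest.fixture(scope="session")
def healthy_profile():
    rng = np.random.default_rng(11)
    return sim.make_subject_profile("HC1", "HC", rng, sim.CHILD_GRID)


@pytest.fixture(scope="session")
def noiseless_profile():
    rng = np.random.default_rng(12)
    return sim.make_subject_profile("HC2", "HC", rng, sim.CHILD_GRID, noise_sd=0.0)


@pytest.fixture(scope="session")
def healthy_recording(healthy_profile, ramp_force):
    return sim.generate_recording(healthy_profile, ramp_force, seed=21)


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_profile, ramp_force):
    return sim.generate_recording(noiseless_profile, ramp_force, seed=22)


@pytest.fixture(scope="session")
def fast_pre_cfg():
    # fewer NMF iterations than the production default; plenty for rank 2
    return PreprocessConfig(nmf_max_iter=200)
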