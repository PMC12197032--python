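import numpy as np
import pytest

import footgrf as fg


@pytest.fixture(scope="session")
def normal_scenario():
    return fg.GaitScenario(n_strides=4)


@pytest.fixture(scope="session")
def normal_trial(normal_scenario):
    """Noiseless barefoot normal-speed walking trial (shared; read-only)."""
    return fg.generate_trial(normal_scenario)


@pytest.fixture(scope="session")
def normal_estimate(normal_trial):
    scn = normal_trial.scenario
    return fg.estimate_grf(normal_trial.markers, normal_trial.static_markers,
                           scn.height, scn.mass)


@pytest.fixture(scope="session")
def static_trial():
    return fg.make_static_trial(fg.GaitScenario())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def interior(trial):
    """Slice trimming half a stride at each end (filter/differentiation edges)."""
    half = trial.markers.n_frames // trial.scenario.n_strides // 2
    return slice(half, -half)
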