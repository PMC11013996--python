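import numpy as np
import pytest
from hypothesis import settings

# derandomized property tests need no example database on disk
settings.register_profile("kinerehab", database=None, deadline=None)
settings.load_profile("kinerehab")

from kinerehab.pipeline import build_feature_table
from kinerehab.recognition import fit_model
from kinerehab.synthetic import MotionScript, Phase, simulate, make_dataset


def single_phase(exercise, rom, period, n_reps, fps=30.0, noise=0.0, seed=0,
                 errors=None, lead_s=0.0, pause_s=0.0):
    """One-exercise simulation used all over the suite."""
    phases = []
    if lead_s:
        phases.append(Phase(None, duration_s=lead_s))
    phases.append(Phase(exercise, rom, period, n_reps,
                        errors=errors or {}, pause_after_s=pause_s))
    return simulate(MotionScript(phases, fps=fps, noise_sd=noise, seed=seed))


@pytest.fixture(scope="session")
def small_trials():
    return make_dataset(8, 4, seed=11)


@pytest.fixture(scope="session")
def small_feature_table(small_trials):
    return build_feature_table(small_trials)


@pytest.fixture(scope="session")
def trained_model(small_feature_table):
    return fit_model(small_feature_table, "SVML", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
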