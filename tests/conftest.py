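import numpy as np
import pandas as pd
import pytest

from emokinetics.config import Clip, RunManifest
from emokinetics.containers import RATING_COLUMNS, RatingPanel

TR = 2.4


def make_panel(rows):
    return RatingPanel(pd.DataFrame(rows, columns=RATING_COLUMNS))


@pytest.fixture
def one_clip_manifest():
    """A single 24 s clip starting at t=0, 20 samples at TR=2.4."""
    return RunManifest("run1", [Clip("c1", 0.0, 24.0)], 10)


@pytest.fixture
def two_clip_manifest():
    return RunManifest("run1", [Clip("c1", 0.0, 24.0), Clip("c2", 24.0, 48.0)],
                       20)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_noiseless_study():
    """Noiseless forward model: 6 emotions, 1 task, deterministic."""
    from emokinetics.simulate import SimulationSpec, simulate_study

    spec = SimulationSpec(n_raters=3, n_emotions=6, n_reliable=6, n_runs=3,
                          n_timepoints_per_run=200, n_participants=4,
                          n_rois=10, snr=np.inf, rng_seed=3,
                          drift_amplitude=0.0, confound_leak=0.0,
                          participant_gain_std=0.0, participant_beta_std=0.0,
                          baseline=0.0, beta_sparsity=0.0)
    return simulate_study(spec, tasks=("perceived",))


@pytest.fixture(scope="session")
def small_noisy_study():
    """snr=5 synthetic study with drift and confounds, both tasks."""
    from emokinetics.simulate import SimulationSpec, simulate_study

    spec = SimulationSpec(n_raters=4, n_emotions=8, n_reliable=5, n_runs=3,
                          n_timepoints_per_run=200, n_participants=6,
                          n_rois=12, snr=5.0, rng_seed=7)
    return simulate_study(spec)
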