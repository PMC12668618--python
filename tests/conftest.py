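import warnings

import numpy as np
import pytest

from cbgtlearn import network as nw
from cbgtlearn.pipeline import StudyConfig, run_study

warnings.filterwarnings("ignore", message="y residual is constant")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_compiled():
    """Compiled default (channel-symmetric) network, shared across tests."""
    return nw.build(nw.NetworkParams())


@pytest.fixture(scope="session")
def baseline_probe(default_compiled):
    """One 200-trial probe block of the naive symmetric network."""
    return nw.simulate_trials(default_compiled, n_trials=200, seed=424242)


@pytest.fixture(scope="session")
def scaled_study(tmp_path_factory):
    """A reduced-scale end-to-end study: GA-sampled cohort, full learning
    sessions with staged freezing, per-stage DDM fits, manifold scoring,
    CCA and driver decomposition.

    Problem sizes are scaled to desk hardware (10 networks, 80-trial probe
    blocks, 7x7 manifold); several behavioral acceptance checks share this
    one cohort.
    """
    outdir = tmp_path_factory.mktemp("study")
    cfg = StudyConfig(
        cohort_size=10,
        outdir=str(outdir),
        master_seed=7,
        ga_eval_trials=40,
        ga_max_iter=40,
        n_learning_trials=15,
        freeze_stages=(2, 4, 6, 15),
        probe_trials_per_stage=80,
        manifold_points=7,
        manifold_seeds=3,
        manifold_trials=150,
        cca_shuffles=20,
        fit_min_trials=40,
    )
    report = run_study(cfg)
    return cfg, report
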