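import warnings

import numpy as np
import pytest

from foldscape.fixtures import default_tether_config, get_fixture
from foldscape.landscape_model import (
    predict_states,
    trap_separation_for_force,
)
from foldscape.synthetic_data import SimConfig, simulate_trace

warnings.filterwarnings("ignore", message="HMM EM did not converge")


@pytest.fixture(scope="session")
def cfg():
    return default_tether_config()


@pytest.fixture(scope="session")
def wt():
    return get_fixture("wt")


@pytest.fixture(scope="session")
def wt_trace(wt, cfg):
    """20 s wild-type trace at a trap separation where all four states are
    populated, with its generating truth."""
    # pick the D that maximizes the smallest state population (all four
    # states simultaneously visible, mirroring the four-Gaussian histograms)
    grid = np.arange(2815.0, 2835.0, 0.5)
    D = max(
        grid, key=lambda d: predict_states(wt, d, cfg).populations.min()
    )
    sim = SimConfig(
        landscape=wt, tether=cfg, seed=1234, duration=20.0,
        trap_separation=D,
    )
    tr, truth = simulate_trace(sim)
    truth["prediction"] = predict_states(wt, D, cfg)
    return tr, truth


@pytest.fixture(scope="session")
def recovery_result():
    """Full simulate -> idealize -> fit recovery on the wild-type fixture
    (the pipeline a real experiment would run), shared across the
    acceptance checks."""
    from foldscape.recovery import run_recovery

    return run_recovery(seed=1)
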