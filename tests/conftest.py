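import numpy as np
import pytest

from cosmotrace import synthetic as syn
from cosmotrace.psf import render_spot


@pytest.fixture(scope="session")
def default_truth():
    return syn.default_truth()


@pytest.fixture(scope="session")
def small_traces(default_truth):
    """100 traces x 800 frames from the packaged two-site ground truth."""
    table, states = syn.simulate_traces(default_truth, 100, 800, seed=11)
    obs = np.stack([table[table["trace"] == i][["signal", "background"]]
                    .to_numpy() for i in range(100)])
    return obs, states


@pytest.fixture(scope="session")
def noiseless_spot():
    """Expected-photon window of one spot (x=5.3, y=4.7, I=1000, bg=2, s=1.3)."""
    truth = dict(x=5.3, y=4.7, intensity=1000.0, background=2.0, sigma=1.3)
    return render_spot((11, 11), truth["x"], truth["y"], truth["intensity"],
                       truth["sigma"], truth["background"]), truth
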