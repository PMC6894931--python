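import numpy as np
import pytest

from multipatch.synthgen import CellParams, ap_train, synth_cluster


@pytest.fixture(scope="session")
def small_cluster():
    """A compact screening experiment with ground truth (3 cells, 8 sweeps)."""
    return synth_cluster(n_cells=3, p_conn=0.5, n_sweeps=8, seed=21)


@pytest.fixture(scope="session")
def default_cluster():
    """One full-size screening experiment (8 cells, 40 sweeps)."""
    return synth_cluster(n_cells=8, p_conn=0.15, n_sweeps=40, seed=42)


@pytest.fixture()
def ap_slot():
    """Clean 4-AP stimulation slot with generator ground truth."""
    trace, spikes, gts = ap_train(CellParams())
    return trace, np.asarray(spikes), gts
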