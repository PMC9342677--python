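import numpy as np
import pytest

from ionstep import fhn_model, pack, synthetic_gate_model


@pytest.fixture(scope="session")
def fhn():
    return fhn_model()


@pytest.fixture(scope="session")
def synth3():
    return synthetic_gate_model(3, seed=7)


@pytest.fixture(scope="session")
def synth5():
    return synthetic_gate_model(5, seed=11)


@pytest.fixture
def fhn_block(fhn):
    """Eight resting FHN cells in SoA storage."""
    return pack(np.tile(fhn.default_initial_state, (8, 1)), "soa", 8,
                fhn.state_names)


def make_block(model, n_cells, layout="soa", lane_width=8, jitter=None, seed=0):
    """Block of cells at the model's initial state, optionally jittered."""
    table = np.tile(model.default_initial_state, (n_cells, 1))
    if jitter:
        rng = np.random.default_rng(seed)
        table = table + jitter * rng.standard_normal(table.shape)
    return pack(table, layout, lane_width, model.state_names)
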