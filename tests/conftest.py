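import numpy as np
import pytest

from ddpcrkit import SimulationParams, TrueConcentrations, simulate_reaction


@pytest.fixture
def default_params():
    return SimulationParams()


@pytest.fixture
def duplex_well(default_params):
    """A default-parameter duplex well with both targets at moderate load,
    together with its ground-truth occupancy."""
    truth = TrueConcentrations(300.0, 400.0)
    reaction, occ_fam, occ_hex = simulate_reaction(
        default_params, truth, seed=11, return_occupancy=True
    )
    return reaction, occ_fam, occ_hex, truth


def true_labels(occ_fam: np.ndarray, occ_hex: np.ndarray) -> np.ndarray:
    """Occupancy-derived class codes matching quantify.LABELS order."""
    fam = occ_fam >= 1
    hex_ = occ_hex >= 1
    labels = np.zeros(occ_fam.size, dtype=np.int8)
    labels[fam & ~hex_] = 1
    labels[~fam & hex_] = 2
    labels[fam & hex_] = 3
    return labels
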