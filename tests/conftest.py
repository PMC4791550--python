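import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from ctbnet.model import CTBNModel


def two_state_cim(q01: float, q10: float) -> np.ndarray:
    return np.array([[[-q01, q01], [q10, -q10]]])


@pytest.fixture
def single_var_model():
    """One 2-state variable with symmetric rate 0.5/h."""
    return CTBNModel(
        variables=["X"],
        n_states={"X": 2},
        parents={"X": ()},
        cims={"X": two_state_cim(0.5, 0.5)},
    )


@pytest.fixture
def chain_model():
    """X1 -> X2: X2 flips fast (2/h) when X1 = 1, slowly (0.05/h) otherwise."""
    cim_x2 = np.array(
        [
            [[-0.05, 0.05], [0.05, -0.05]],  # X1 = 0
            [[-2.0, 2.0], [2.0, -2.0]],  # X1 = 1
        ]
    )
    return CTBNModel(
        variables=["X1", "X2"],
        n_states={"X1": 2, "X2": 2},
        parents={"X1": (), "X2": ("X1",)},
        cims={"X1": two_state_cim(0.3, 0.3), "X2": cim_x2},
    )
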