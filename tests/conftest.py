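import math

import numpy as np
import pytest

from podosim import ModelParameters, load_parameters
from podosim.state import Cell, Podium, SimulationState


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_test_cell(params, center=(0.0, 0.0), height=None, R=None,
                   podia=(), phase=1, cell_id=1, v_target=None):
    """Cell with explicit geometry for deterministic fixtures."""
    R = R if R is not None else params.r0
    height = height if height is not None else 0.75 * R
    vt = v_target if v_target is not None else (4.0 / 3.0) * math.pi * R**3
    return Cell(center=np.asarray(center, float), R=R, V_target=vt,
                height=height, phase=phase,
                podia=[Podium(*p) if isinstance(p, tuple) else p
                       for p in podia],
                id=cell_id)


@pytest.fixture()
def two_cell_state(params):
    c1 = make_test_cell(params, (0.0, 0.0), cell_id=1)
    c2 = make_test_cell(params, (8.5, 0.0), cell_id=2)
    return SimulationState.from_cells(params, [c1, c2])
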