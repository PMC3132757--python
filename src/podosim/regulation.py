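"""Density-dependent regulation of growth, migration and morphology.

Contact inhibition enters the model through three regulated quantities --
the target-volume growth rate, the independent podium inactivation rate
and the number-of-podia offset -- each a ramp in the number of nearest
neighbours: constant at low and high density with a linear transition.
The growth rate uses the proliferation bounds (default 4:5 neighbours);
the two podia quantities share the migration bounds (default 1:3), since
they are varied jointly as one "random podia activity" knob.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters
from .state import Cell, RegulatedValues, SimulationState

__all__ = ["ramp", "regulate_cell", "regulate_state"]


def ramp(v_low, v_high, n_low, n_high, n):
    """Piecewise-linear ramp between the low- and high-density plateaus.

    Works on scalars or arrays of ``n``.  With ``n_low == n_high`` the ramp
    degenerates to a step at that neighbour count.
    """
    if n_low > n_high:
        raise ValueError("ramp bounds require n_low <= n_high")
    n = np.asarray(n, dtype=float)
    if n_low == n_high:
        out = np.where(n < n_low, v_low, v_high)
    else:
        frac = np.clip((n - n_low) / (n_high - n_low), 0.0, 1.0)
        out = v_low + (v_high - v_low) * frac
    return out if out.ndim else float(out)


def regulate_cell(cell: Cell, state: SimulationState) -> Cell:
    """Set a cell's regulated values from its current neighbour count."""
    from .state import neighbor_count

    p = state.params
    n = neighbor_count(cell, state)
    cell.reg = RegulatedValues(
        growth_rate=ramp(p.dvdt_lo, p.dvdt_hi, p.n_prolif_lo, p.n_prolif_hi, n),
        r_ind=ramp(p.r_ind_lo, p.r_ind_hi, p.n_podia_lo, p.n_podia_hi, n),
        n_off=ramp(p.n_off_lo, p.n_off_hi, p.n_podia_lo, p.n_podia_hi, n),
    )
    return cell


def regulate_state(state: SimulationState, counts=None) -> None:
    """Vectorised regulation of the whole population."""
    p = state.params
    if counts is None:
        counts = state.neighbors
    state.reg_growth = ramp(p.dvdt_lo, p.dvdt_hi,
                            p.n_prolif_lo, p.n_prolif_hi, counts)
    state.reg_rind = ramp(p.r_ind_lo, p.r_ind_hi,
                          p.n_podia_lo, p.n_podia_hi, counts)
    state.reg_noff = ramp(p.n_off_lo, p.n_off_hi,
                          p.n_podia_lo, p.n_podia_hi, counts)
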