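"""Five-phase cell cycle with four checkpoints.

Phases: 0 (post-division radius adjustment, lower volume checkpoint),
1 (growing), 2 (quiescent, actual volume lagging behind target), 3
(pre-division: growth stopped, podia inactivated, upper volume
checkpoint), 4 (ready to divide once all podia are deleted).

Target-volume growth is a probabilistic increment process: with
probability 1 - exp(-m_inc dt) per step the target volume jumps by
(regulated rate)/m_inc (60 um^3 with the default 1200 um^3/d at 20
increments per day), capped at the division volume V_max.  Division
produces two daughters of half the parent target volume, placed
symmetrically about the parent centre along the stored division axis so
that the daughter spheres just touch, each starting in phase 0 with no
podia.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .params import ModelParameters
from .state import Cell, RegulatedValues

__all__ = ["grow_target_volume", "advance_phase", "divide"]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def grow_target_volume(cell: Cell, params: ModelParameters, dt: float,
                       rng) -> Cell:
    """Stochastic target-volume increment (phase 1 only)."""
    if cell.phase != 1:
        return cell
    rate = cell.reg.growth_rate if cell.reg is not None else params.dvdt_lo
    if rate <= 0:
        return cell
    if rng.uniform() < -math.expm1(-params.m_inc * dt):
        cell.V_target = min(cell.V_target + rate / params.m_inc, params.v_max)
    return cell


def advance_phase(cell: Cell, params: ModelParameters) -> Cell:
    """Apply the checkpoint transitions for one cell.

    0 -> 1 once the actual volume has caught up with the target (within the
    lag fraction); 1 <-> 2 on the compression checkpoint; 1 -> 3 on the
    upper volume checkpoint (podia switched off); 3 -> 4 once all podia are
    deleted.
    """
    lag = (cell.V_target - cell.V_actual) / cell.V_target
    if cell.phase == 0:
        if lag <= params.lag_frac:
            cell.phase = 1
    elif cell.phase == 1:
        if (cell.V_target >= params.v_max
                and cell.V_actual >= (1.0 - params.lag_frac) * params.v_max):
            cell.phase = 3
            for p in cell.podia:
                p.active = False
        elif lag > params.lag_frac:
            cell.phase = 2
    elif cell.phase == 2:
        if lag <= params.lag_frac:
            cell.phase = 1
    elif cell.phase == 3:
        for p in cell.podia:
            p.active = False
        if not cell.podia:
            cell.phase = 4
    return cell


def divide(cell: Cell, params: ModelParameters, rng) -> Tuple[Cell, Cell]:
    """Split a phase-4 cell into two daughters along its division axis."""
    if cell.phase != 4:
        raise ValueError("divide() requires a cell in phase 4")
    v_half = cell.V_target / 2.0
    r_d = (v_half / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
    axis = cell.division_axis
    if axis is None:
        axis = float(rng.uniform(0.0, math.pi))
    u = np.array([math.cos(axis), math.sin(axis)])
    from .mechanics import equilibrium_heights

    z = float(equilibrium_heights(params, np.array([r_d]),
                                  np.array([v_half]), np.array([0.0]))[0])
    daughters = []
    for sign in (1.0, -1.0):
        # each daughter remembers its outward direction; the first podium
        # it regrows points that way, so the pair elongates apart (daughter
        # podia align to each other along the division axis)
        out_axis = axis if sign > 0 else (axis + math.pi) % (2.0 * math.pi)
        daughters.append(Cell(
            center=cell.center + sign * r_d * u, R=r_d, V_target=v_half,
            height=z, phase=0, podia=[],
            reg=RegulatedValues(0.0, 0.0, 0.0) if cell.reg is None else
            RegulatedValues(cell.reg.growth_rate, cell.reg.r_ind,
                            cell.reg.n_off),
            division_axis=out_axis, id=0))
    return daughters[0], daughters[1]
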