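"""Domain types: podia, cells, the array-backed simulation state.

The public types :class:`Podium` and :class:`Cell` are plain dataclasses
used at API boundaries (construction, snapshots, metrics, tests).  The
engine operates on :class:`SimulationState`, a struct-of-arrays container
(positions, radii, padded per-cell podium tables) so that the mechanical
and geometric kernels can run vectorised over the whole population.
Conversion between the two views is lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import List, Optional

import numpy as np

from .geometry import cell_primitives, min_shape_distance
from .params import ModelParameters

__all__ = ["Podium", "Cell", "SimulationState", "shape_distance", "neighbor_count"]

#: maximum podia per cell in the padded arrays.  The regulated offset keeps
#: the mean at 2-3.5; eight slots are never exhausted in practice and a
#: generation attempt on a full table is silently rejected.
MAX_PODIA = 8


@dataclass
class Podium:
    """A single podium: planar direction, length, activity and precedence.

    ``length`` is measured from half the adhesion radius to the centre of
    the podium tip; a freshly generated podium therefore starts at half the
    adhesion radius, i.e. its tip sits at the cell-body edge.
    """

    angle: float
    length: float
    active: bool = True
    precedence: int = 1

    def __post_init__(self) -> None:
        self.angle = float(self.angle) % (2.0 * math.pi)
        if self.length < 0:
            raise ValueError("podium length must be >= 0")
        if self.precedence < 1:
            raise ValueError("podium precedence must be >= 1")


@dataclass
class RegulatedValues:
    """Density-regulated per-cell control values."""

    growth_rate: float  # um^3/min
    r_ind: float        # 1/min
    n_off: float        # dimensionless

    @classmethod
    def low_density(cls, params: ModelParameters) -> "RegulatedValues":
        return cls(params.dvdt_lo, params.r_ind_lo, params.n_off_lo)


@dataclass
class Cell:
    center: np.ndarray
    R: float
    V_target: float
    height: float
    phase: int = 1
    podia: List[Podium] = dc_field(default_factory=list)
    reg: Optional[RegulatedValues] = None
    division_axis: Optional[float] = None
    V_actual: Optional[float] = None
    id: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.R <= 0:
            raise ValueError("cell radius must be > 0")
        if not 0.0 <= self.height <= self.R:
            raise ValueError("cell centre height must lie in [0, R]")
        if self.phase not in (0, 1, 2, 3, 4):
            raise ValueError("phase must be one of 0..4")
        if self.V_actual is None:
            # isolated default: sphere volume less the substrate cap
            h = self.R - self.height
            cap = math.pi * h * h * (3.0 * self.R - h) / 3.0
            self.V_actual = (4.0 / 3.0) * math.pi * self.R**3 - cap

    @property
    def adhesion_radius(self) -> float:
        return math.sqrt(max(self.R**2 - self.height**2, 0.0))

    def tip_radius(self, params: ModelParameters) -> float:
        return params.cone_tip_frac * self.adhesion_radius

    def n_active(self) -> int:
        return sum(1 for p in self.podia if p.active)

    def primitives(self, params: ModelParameters):
        return cell_primitives(
            self.center, self.adhesion_radius, self.tip_radius(params),
            [(p.angle, p.length) for p in self.podia])


def make_cell(params: ModelParameters, center=(0.0, 0.0), *, phase: int = 1,
              height: Optional[float] = None, cell_id: int = 0) -> Cell:
    """A fresh cell with the seeding radius and low-density regulation."""
    from .mechanics import equilibrium_heights  # local import, avoids cycle

    R = params.r0
    if height is None:
        height = float(equilibrium_heights(
            params, np.array([R]), np.array([params.v0]), np.array([0.0]))[0])
    return Cell(center=np.asarray(center, float), R=R, V_target=params.v0,
                height=height, phase=phase,
                reg=RegulatedValues.low_density(params), id=cell_id)


def shape_distance(cell_i: Cell, cell_j: Cell, params: ModelParameters) -> float:
    """Minimum distance between the footprints of two distinct cells (um).

    The footprint is the union of the body disc (radius = adhesion radius)
    and the podium cones; overlapping shapes give 0.
    """
    if cell_i is cell_j or (cell_i.id == cell_j.id and cell_i.id != 0):
        raise ValueError("shape_distance requires two distinct cells")
    d = min_shape_distance(cell_i.primitives(params), cell_j.primitives(params))
    return max(d, 0.0)


def neighbor_count(cell: Cell, state: "SimulationState") -> int:
    """Number of other cells within ``d_nn`` of this cell.

    A cell j is a neighbour of i when j's body disc lies within ``d_nn``
    of i's footprint (body disc or podium cones) or vice versa; the
    relation is symmetric.  Podium-podium proximity alone does not count:
    long podia sweeping past each other do not crowd the cell bodies, and
    counting them would saturate the density regulation in any spread
    colony.
    """
    params = state.params
    prims = cell.primitives(params)
    body = prims[:1]
    n = 0
    for other in state.cells():
        if other.id == cell.id:
            continue
        oprims = other.primitives(params)
        d = min(min_shape_distance(prims, oprims[:1]),
                min_shape_distance(body, oprims))
        if d <= params.d_nn:
            n += 1
    return n


class SimulationState:
    """Array-backed population state at one instant of simulated time.

    Per-cell arrays (length ``n``):

    ``x, y``        centre position (um)
    ``R``           body radius (um)
    ``z``           centre height above the substrate (um)
    ``vt``          target volume (um^3)
    ``va``          actual, cap-reduced volume (um^3)
    ``phase``       cell-cycle phase 0..4
    ``reg_*``       regulated growth rate / r_ind / n_off
    ``div_axis``    stored division orientation (rad; NaN = none)
    ``ids``         unique, stable cell identifiers

    Per-podium padded arrays (shape ``(n, MAX_PODIA)``): ``p_ang, p_len,
    p_act, p_prec, p_on`` where ``p_on`` marks existing slots.
    """

    def __init__(self, params: ModelParameters, substrate=None, rng=None,
                 t: float = 0.0):
        from .substrates import plain  # local import, avoids cycle

        self.params = params
        self.substrate = substrate if substrate is not None else plain()
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.t = float(t)
        self._alloc(0)
        self.next_id = 1
        self.neighbors = np.zeros(0, dtype=np.int64)
        self._nbr_age = 10**9  # force a refresh on the first step

    def _alloc(self, n: int) -> None:
        self.x = np.zeros(n)
        self.y = np.zeros(n)
        self.R = np.zeros(n)
        self.z = np.zeros(n)
        self.vt = np.zeros(n)
        self.va = np.zeros(n)
        self.phase = np.zeros(n, dtype=np.int8)
        self.reg_growth = np.zeros(n)
        self.reg_rind = np.zeros(n)
        self.reg_noff = np.zeros(n)
        self.div_axis = np.full(n, np.nan)
        self.ids = np.zeros(n, dtype=np.int64)
        self.p_ang = np.zeros((n, MAX_PODIA))
        self.p_len = np.zeros((n, MAX_PODIA))
        self.p_act = np.zeros((n, MAX_PODIA), dtype=bool)
        self.p_prec = np.ones((n, MAX_PODIA), dtype=np.int32)
        self.p_on = np.zeros((n, MAX_PODIA), dtype=bool)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def a(self) -> np.ndarray:
        """Adhesion radii sqrt(R^2 - z^2)."""
        return np.sqrt(np.maximum(self.R**2 - self.z**2, 0.0))

    @property
    def tip_r(self) -> np.ndarray:
        return self.params.cone_tip_frac * self.a

    def n_podia(self) -> np.ndarray:
        return self.p_on.sum(axis=1)

    def n_active(self) -> np.ndarray:
        return (self.p_on & self.p_act).sum(axis=1)

    # ------------------------------------------------------------------
    def add_cells(self, cells: List[Cell]) -> None:
        """Append Cell objects, assigning ids where missing."""
        arrays = {k: [getattr(self, k)] for k in
                  ("x", "y", "R", "z", "vt", "va", "phase", "reg_growth",
                   "reg_rind", "reg_noff", "div_axis", "ids")}
        pod = {k: [getattr(self, k)] for k in
               ("p_ang", "p_len", "p_act", "p_prec", "p_on")}
        m = len(cells)
        new = {k: np.zeros(m) for k in ("x", "y", "R", "z", "vt", "va",
                                        "reg_growth", "reg_rind", "reg_noff")}
        new["phase"] = np.zeros(m, dtype=np.int8)
        new["div_axis"] = np.full(m, np.nan)
        new["ids"] = np.zeros(m, dtype=np.int64)
        pn = {"p_ang": np.zeros((m, MAX_PODIA)),
              "p_len": np.zeros((m, MAX_PODIA)),
              "p_act": np.zeros((m, MAX_PODIA), dtype=bool),
              "p_prec": np.ones((m, MAX_PODIA), dtype=np.int32),
              "p_on": np.zeros((m, MAX_PODIA), dtype=bool)}
        for i, c in enumerate(cells):
            reg = c.reg or RegulatedValues.low_density(self.params)
            new["x"][i], new["y"][i] = c.center
            new["R"][i] = c.R
            new["z"][i] = c.height
            new["vt"][i] = c.V_target
            new["va"][i] = c.V_actual
            new["phase"][i] = c.phase
            new["reg_growth"][i] = reg.growth_rate
            new["reg_rind"][i] = reg.r_ind
            new["reg_noff"][i] = reg.n_off
            new["div_axis"][i] = np.nan if c.division_axis is None else c.division_axis
            cid = c.id if c.id else self.next_id
            new["ids"][i] = cid
            self.next_id = max(self.next_id, cid + 1)
            if len(c.podia) > MAX_PODIA:
                raise ValueError(f"cell {cid}: more than {MAX_PODIA} podia")
            for j, p in enumerate(c.podia):
                pn["p_ang"][i, j] = p.angle
                pn["p_len"][i, j] = p.length
                pn["p_act"][i, j] = p.active
                pn["p_prec"][i, j] = p.precedence
                pn["p_on"][i, j] = True
        if len(set(new["ids"].tolist()) | set(self.ids.tolist())) != self.n + m:
            raise ValueError("cell identifiers must be unique")
        for k in arrays:
            arrays[k].append(new[k])
            setattr(self, k, np.concatenate(arrays[k]))
        for k in pod:
            pod[k].append(pn[k])
            setattr(self, k, np.concatenate(pod[k], axis=0))
        old = self.neighbors if len(self.neighbors) == self.n - m \
            else np.zeros(self.n - m, dtype=np.int64)
        self.neighbors = np.concatenate([old, np.zeros(m, dtype=np.int64)])
        self._nbr_age = 10**9  # stale after membership changes

    def cells(self) -> List[Cell]:
        """Materialise the population as Cell objects (copies)."""
        out = []
        for i in range(self.n):
            podia = [Podium(self.p_ang[i, j], self.p_len[i, j],
                            bool(self.p_act[i, j]), int(self.p_prec[i, j]))
                     for j in range(MAX_PODIA) if self.p_on[i, j]]
            div = None if np.isnan(self.div_axis[i]) else float(self.div_axis[i])
            out.append(Cell(
                center=np.array([self.x[i], self.y[i]]), R=float(self.R[i]),
                V_target=float(self.vt[i]), height=float(self.z[i]),
                phase=int(self.phase[i]), podia=podia,
                reg=RegulatedValues(float(self.reg_growth[i]),
                                    float(self.reg_rind[i]),
                                    float(self.reg_noff[i])),
                division_axis=div, V_actual=float(self.va[i]),
                id=int(self.ids[i])))
        return out

    @classmethod
    def from_cells(cls, params: ModelParameters, cells: List[Cell],
                   substrate=None, rng=None, t: float = 0.0) -> "SimulationState":
        st = cls(params, substrate=substrate, rng=rng, t=t)
        st.add_cells(cells)
        return st

    def copy(self) -> "SimulationState":
        import copy as _copy

        st = SimulationState.__new__(SimulationState)
        st._nbr_age = self._nbr_age
        st.params = self.params
        st.substrate = self.substrate
        st.rng = _copy.deepcopy(self.rng)
        st.t = self.t
        st.next_id = self.next_id
        for k in ("x", "y", "R", "z", "vt", "va", "phase", "reg_growth",
                  "reg_rind", "reg_noff", "div_axis", "ids", "p_ang",
                  "p_len", "p_act", "p_prec", "p_on", "neighbors"):
            setattr(st, k, getattr(self, k).copy())
        return st
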