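"""Time-stepping engine.

Each iteration follows a fixed order: first podia are moved (tip dynamics,
stochastic generation/inactivation, elimination, overlap resolution and
groove alignment), second the cell bodies (force computation, coupled
velocity solve, explicit Euler update and confinement), third the radii
(radius velocity, quasi-static height re-balance), and finally phenotype
and proliferation states (neighbour counts, regulation, target-volume
growth, phase transitions and divisions).

Podium tips adhere to the substrate: when a body translates, each tip
keeps its laboratory position and the podium's angle and length are
re-derived from the new base.  A single seeded random stream is consumed
in a fixed order (cells ascending, podia by slot index), which makes runs
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import neighbor_pairs_kernel
from .guidance import align_to_grooves, resolve_overlaps
from .mechanics import body_forces, equilibrium_heights, solve_velocities
from .metrics import consensus_orientation_angles
from .params import ModelParameters
from .regulation import regulate_state
from .state import MAX_PODIA, Cell, SimulationState, make_cell
from .substrates import SubstratePattern, plain

__all__ = ["step", "run", "seed_state", "EngineError", "Snapshot", "Trajectory"]

_MINUTES_PER_DAY = 1440.0
#: numerical sanity bound: podium-driven speeds top out near 2 um/min and
#: contact transients at tens of um/min (tamed by displacement clipping);
#: a non-finite state or anything beyond this signals a genuine blow-up
_SPEED_LIMIT = 1e5
_MAX_DISP = 1.0      # um, displacement cap per force evaluation
_NEIGHBOR_REFRESH = 3  # steps between full neighbour-count refreshes
_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


class EngineError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# podium sub-steps (vectorised)
# ----------------------------------------------------------------------

def _tips_step(state: SimulationState) -> None:
    # exact exponential propagator of the linear tip equation
    p = state.params
    act = state.p_on & state.p_act
    l_inf = np.where(act, p.f_p / p.k_spring, 0.0)
    decay = math.exp(-p.k_spring * p.dt / p.gamma_p)
    newlen = np.maximum(l_inf + (state.p_len - l_inf) * decay, 0.0)
    state.p_len = np.where(state.p_on, newlen, 0.0)


def _generation_step(state: SimulationState) -> None:
    from .podia import sample_podium_angle

    p = state.params
    n = state.n
    p_ev = -math.expm1(-p.lambda_np * p.dt)
    events = state.rng.random(n) < p_ev
    accept = state.rng.random(n)
    from .podia import generation_probability

    n_act = state.n_active()
    p_gen = generation_probability(n_act, state.reg_noff,
                                   p.gen_accept_scale)
    ok = (events & (accept < p_gen) & (state.phase != 3) & (state.phase != 4)
          & (state.n_podia() < MAX_PODIA))
    a = state.a
    for i in np.flatnonzero(ok):
        existing = state.p_ang[i, state.p_on[i]]
        if existing.size == 0 and not np.isnan(state.div_axis[i]):
            # a newborn daughter sprouts its first podium along its outward
            # division axis, so sibling pairs elongate apart and separate
            ang = float(state.div_axis[i] % (2.0 * math.pi))
            state.div_axis[i] = np.nan
        else:
            ang = sample_podium_angle(existing, p, state.rng)
        slot = int(np.flatnonzero(~state.p_on[i])[0])
        state.p_ang[i, slot] = ang
        state.p_len[i, slot] = a[i] / 2.0
        state.p_act[i, slot] = True
        state.p_prec[i, slot] = 1
        state.p_on[i, slot] = True


def _inactivation_step(state: SimulationState) -> None:
    p = state.params
    n = state.n
    p_ev = -math.expm1(-p.lambda_np * p.dt)
    events = state.rng.random(n) < p_ev
    from .podia import lambda_inactivation_probability

    p_lam = np.where(events,
                     lambda_inactivation_probability(state.n_active(),
                                                     state.reg_noff), 0.0)
    p_r = -np.expm1(-state.reg_rind * p.dt)
    prob = p_lam + p_r - p_lam * p_r
    draws = state.rng.random((n, MAX_PODIA))
    hit = state.p_on & state.p_act & (draws < prob[:, None])
    state.p_act[hit] = False


def _elimination_step(state: SimulationState) -> None:
    gone = state.p_on & ~state.p_act & (state.p_len < state.a[:, None])
    state.p_on[gone] = False
    state.p_len[~state.p_on] = 0.0
    state.p_act[~state.p_on] = False
    state.p_prec[~state.p_on] = 1


# ----------------------------------------------------------------------
# neighbour counting
# ----------------------------------------------------------------------

def _broad_pairs(state: SimulationState):
    """Cell pairs within mutual footprint reach plus the d_nn margin."""
    n = state.n
    if n < 2:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64))
    a = state.a
    ext = a[:, None] / 2.0 + np.where(state.p_on, state.p_len, 0.0) \
        + state.tip_r[:, None]
    reach = np.maximum(a, ext.max(axis=1))
    tree = cKDTree(np.column_stack([state.x, state.y]))
    raw = tree.query_pairs(
        2.0 * float(reach.max()) + state.params.d_nn + 1.0,
        output_type="ndarray")
    if raw.size == 0:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64))
    ii, jj = raw[:, 0].astype(np.int64), raw[:, 1].astype(np.int64)
    d = np.hypot(state.x[jj] - state.x[ii], state.y[jj] - state.y[ii])
    keep = d <= reach[ii] + reach[jj] + state.params.d_nn
    return ii[keep], jj[keep]


def _neighbor_counts(state: SimulationState, pairs=None) -> np.ndarray:
    n = state.n
    counts = np.zeros(n, dtype=np.int64)
    if n < 2:
        return counts
    p = state.params
    a = state.a
    ext = a[:, None] / 2.0 + np.where(state.p_on, state.p_len, 0.0) \
        + state.tip_r[:, None]
    reach = np.maximum(a, ext.max(axis=1))
    if pairs is None:
        tree = cKDTree(np.column_stack([state.x, state.y]))
        raw = tree.query_pairs(2.0 * float(reach.max()) + p.d_nn,
                               output_type="ndarray")
        if raw.size == 0:
            return counts
        ii, jj = raw[:, 0].astype(np.int64), raw[:, 1].astype(np.int64)
    else:
        ii, jj = pairs
    d = np.hypot(state.x[jj] - state.x[ii], state.y[jj] - state.y[ii])
    keep = d <= reach[ii] + reach[jj] + p.d_nn
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        return counts
    near = neighbor_pairs_kernel(ii, jj, state.x, state.y, a, state.tip_r,
                                 state.p_ang, state.p_len, state.p_on,
                                 p.d_nn)
    np.add.at(counts, ii[near], 1)
    np.add.at(counts, jj[near], 1)
    return counts


# ----------------------------------------------------------------------
# proliferation (vectorised phases and divisions)
# ----------------------------------------------------------------------

def _growth_step(state: SimulationState) -> None:
    p = state.params
    draws = state.rng.random(state.n)
    grow = ((state.phase == 1) & (state.reg_growth > 0)
            & (draws < -math.expm1(-p.m_inc * p.dt)))
    state.vt = np.where(grow,
                        np.minimum(state.vt + state.reg_growth / p.m_inc,
                                   p.v_max),
                        state.vt)


def _phase_step(state: SimulationState) -> None:
    p = state.params
    lag = (state.vt - state.va) / state.vt
    # 0 -> 1
    state.phase[(state.phase == 0) & (lag <= p.lag_frac)] = 1
    # 1 -> 3 (upper volume checkpoint), recording the division axis
    to3 = ((state.phase == 1) & (state.vt >= p.v_max)
           & (state.va >= (1.0 - p.lag_frac) * p.v_max))
    for i in np.flatnonzero(to3):
        angs = state.p_ang[i, state.p_on[i]]
        state.div_axis[i] = (consensus_orientation_angles(angs)
                             if angs.size else np.nan)
    state.phase[to3] = 3
    # 1 <-> 2 (compression checkpoint)
    state.phase[(state.phase == 1) & (lag > p.lag_frac)] = 2
    state.phase[(state.phase == 2) & (lag <= p.lag_frac)] = 1
    # phase 3: podia stay off; 3 -> 4 once all podia are deleted
    in3 = state.phase == 3
    state.p_act[in3] = False
    state.phase[in3 & (state.n_podia() == 0)] = 4


def _division_step(state: SimulationState) -> None:
    p = state.params
    idx = np.flatnonzero(state.phase == 4)
    if idx.size == 0:
        return
    new_cells: List[Cell] = []
    for i in idx:
        v_half = state.vt[i] / 2.0
        r_d = (v_half / _FOUR_THIRDS_PI) ** (1.0 / 3.0)
        axis = state.div_axis[i]
        if np.isnan(axis):
            axis = state.rng.uniform(0.0, math.pi)
        ux, uy = math.cos(axis), math.sin(axis)
        z = float(equilibrium_heights(p, np.array([r_d]), np.array([v_half]),
                                      np.array([0.0]))[0])
        # first daughter replaces the parent slot
        state.x[i] += r_d * ux
        state.y[i] += r_d * uy
        state.R[i] = r_d
        state.z[i] = z
        state.vt[i] = v_half
        state.va[i] = v_half
        state.phase[i] = 0
        state.div_axis[i] = axis  # outward direction for the first podium
        state.p_on[i] = False
        state.p_act[i] = False
        state.p_len[i] = 0.0
        state.p_prec[i] = 1
        state.ids[i] = state.next_id
        state.next_id += 1
        sib = Cell(center=np.array([state.x[i] - 2.0 * r_d * ux,
                                    state.y[i] - 2.0 * r_d * uy]),
                   R=r_d, V_target=v_half, height=z, phase=0, podia=[],
                   V_actual=v_half, division_axis=(axis + math.pi) % (2 * math.pi),
                   id=0)
        new_cells.append(sib)
    state.add_cells(new_cells)


# ----------------------------------------------------------------------
# full step
# ----------------------------------------------------------------------

def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one time step ``dt``."""
    p = state.params
    dt = p.dt
    if state.n:
        # (1) podia
        _tips_step(state)
        _generation_step(state)
        _inactivation_step(state)
        _elimination_step(state)
        # one broad-phase pair list serves both guidance and the neighbour
        # classification at the end of the step
        pairs = _broad_pairs(state)
        resolve_overlaps(state, pairs)
        align_to_grooves(state)
        # (2) bodies and (3) radii, with adaptive sub-stepping: stiff
        # post-division transients are relaxed by capping the displacement
        # per force evaluation instead of overshooting the Euler step
        tipd = state.a[:, None] / 2.0 + state.p_len
        tipx = state.x[:, None] + tipd * np.cos(state.p_ang)
        tipy = state.y[:, None] + tipd * np.sin(state.p_ang)
        e = np.stack([np.cos(state.p_ang), np.sin(state.p_ang)], axis=-1)
        w = np.where(state.p_on, p.k_spring * state.p_len, 0.0)
        tractions = (w[:, :, None] * e).sum(axis=1)
        # at most two force evaluations: a bounded relaxation substep when
        # a stiff transient (fresh division) is present, then the remainder
        # of the step with per-cell displacement clipping
        remaining = dt
        for _sub in range(2):
            F, FR, cache = body_forces(state)
            v, vR = solve_velocities(state, F, FR, cache, tractions)
            speed = np.hypot(v[:, 0], v[:, 1])
            vmax = float(max(speed.max(initial=0.0),
                             np.abs(vR).max(initial=0.0)))
            if not np.isfinite(vmax) or vmax > _SPEED_LIMIT:
                i = int(speed.argmax())
                raise EngineError(
                    f"numerical divergence: cell {state.ids[i]} speed "
                    f"{vmax:.2f} um/min exceeds {_SPEED_LIMIT} at "
                    f"t={state.t:.3f} d")
            if _sub == 0 and vmax * remaining > _MAX_DISP:
                h = _MAX_DISP / vmax
            else:
                h = remaining
            fac = np.minimum(1.0, _MAX_DISP / np.maximum(speed * h, 1e-12))
            state.x += h * v[:, 0] * fac
            state.y += h * v[:, 1] * fac
            if p.boundary_radius is not None:
                r = np.hypot(state.x, state.y)
                out = r > p.boundary_radius
                if out.any():
                    bfac = p.boundary_radius / r[out]
                    state.x[out] *= bfac
                    state.y[out] *= bfac
            state.R = np.maximum(
                state.R + np.clip(h * vR, -_MAX_DISP, _MAX_DISP), 1.0)
            other_caps = _pair_cap_volumes(state, cache)
            state.z = equilibrium_heights(p, state.R, state.vt, other_caps)
            remaining -= h
            if remaining <= 1e-12:
                break
        # re-anchor podia to their (substrate-adhered) lab-frame tips
        a_new = state.a
        dx = tipx - state.x[:, None]
        dy = tipy - state.y[:, None]
        newang = np.arctan2(dy, dx) % (2.0 * math.pi)
        newlen = np.maximum(np.hypot(dx, dy) - a_new[:, None] / 2.0, 0.0)
        state.p_ang = np.where(state.p_on, newang, 0.0)
        state.p_len = np.where(state.p_on, newlen, 0.0)
        # refresh actual volumes for the checkpoints
        from .mechanics import _population_geometry

        state.va = _population_geometry(state)["va"]
        # (4) phenotype and proliferation; the neighbour classification is
        # refreshed every few minutes (regulation ramps vary on the hour
        # scale, and a full footprint-distance pass is expensive)
        if state._nbr_age >= _NEIGHBOR_REFRESH or len(state.neighbors) != state.n:
            state.neighbors = _neighbor_counts(state, pairs)
            state._nbr_age = 0
        else:
            state._nbr_age += 1
        regulate_state(state)
        _growth_step(state)
        _phase_step(state)
        _division_step(state)
    state.t += dt / _MINUTES_PER_DAY
    return state


def _pair_cap_volumes(state, cache):
    """Cell-cell cap volume already removed per cell (for the z balance)."""
    out = np.zeros(state.n)
    ii, jj = cache["ii"], cache["jj"]
    if ii.size:
        hi, hj = cache["hi"], cache["hj"]
        np.add.at(out, ii, np.pi * hi * hi * (3.0 * state.R[ii] - hi) / 3.0)
        np.add.at(out, jj, np.pi * hj * hj * (3.0 * state.R[jj] - hj) / 3.0)
    return out


# ----------------------------------------------------------------------
# runs
# ----------------------------------------------------------------------

@dataclass
class Snapshot:
    t: float
    state: SimulationState


@dataclass
class Trajectory:
    params: ModelParameters
    seed: int
    snapshots: List[Snapshot] = field(default_factory=list)

    def times(self):
        return [s.t for s in self.snapshots]

    def final(self) -> SimulationState:
        return self.snapshots[-1].state


def seed_state(params: ModelParameters, *, seed: int = 0,
               substrate: Optional[SubstratePattern] = None,
               n_init: int = 1, seed_radius: float = 0.0) -> SimulationState:
    """Initial state: ``n_init`` cells, at the origin or uniform in a disc."""
    rng = np.random.default_rng(seed)
    state = SimulationState(params, substrate=substrate or plain(), rng=rng)
    cells = []
    for _ in range(n_init):
        if n_init == 1 or seed_radius <= 0:
            pos = (0.0, 0.0) if n_init == 1 else \
                tuple(rng.uniform(-params.r0, params.r0, 2))
        else:
            while True:
                pos = tuple(rng.uniform(-seed_radius, seed_radius, 2))
                if math.hypot(*pos) <= seed_radius:
                    break
        cells.append(make_cell(params, pos))
    state.add_cells(cells)
    state.neighbors = _neighbor_counts(state)
    regulate_state(state)
    return state


def run(params: ModelParameters, *, days: float, seed: int = 0,
        substrate: Optional[SubstratePattern] = None, n_init: int = 1,
        seed_radius: float = 0.0, snapshot_every: Optional[float] = None,
        progress=None) -> Trajectory:
    """Run a simulation and collect snapshots.

    ``snapshot_every`` is the cadence in simulated minutes (default: one
    per simulated day).  The initial state is always the first snapshot.
    Identical seeds produce identical trajectories.
    """
    state = seed_state(params, seed=seed, substrate=substrate,
                       n_init=n_init, seed_radius=seed_radius)
    traj = Trajectory(params=params, seed=seed)
    traj.snapshots.append(Snapshot(state.t, state.copy()))
    n_steps = int(round(days * _MINUTES_PER_DAY / params.dt))
    snap_every = snapshot_every if snapshot_every is not None \
        else _MINUTES_PER_DAY
    snap_stride = max(int(round(snap_every / params.dt)), 1)
    for k in range(1, n_steps + 1):
        step(state)
        if k % snap_stride == 0 or k == n_steps:
            traj.snapshots.append(Snapshot(state.t, state.copy()))
            if progress is not None:
                progress(state)
    return traj
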