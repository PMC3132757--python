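"""Cell-body mechanics: contact geometry, energies, forces, velocities.

Cells are compressible elastic spheres living on a rigid, flat, adhesive
substrate.  Per cell the body energy decomposes into

* adhesion       E_A = -(eps_cc * sum_j A_ij + eps_cs * A_is)
* deformation    E_D = sum_contacts (8/15) E* sqrt(R_eff) delta^{5/2}   (Hertz)
* compression    E_C = (K/2) (V_actual - V_target)^2 / V_target

with 1/E* = 2(1-nu^2)/E for cell-cell contacts and (1-nu^2)/E against the
rigid substrate, and R_eff the reduced radius.  V_actual is the sphere
volume less all spherical caps cut off by neighbours and the substrate.

Forces on cell centres and radii are the exact analytic gradients of the
population energy (pair terms counted once); the over-damped velocity
solve couples cells through cell-cell friction proportional to the shared
contact area and is performed with conjugate gradients on the symmetric
positive-definite friction matrix.

The centre height above the substrate is not a dynamic variable: it is
re-balanced quasi-statically each step by root-finding the normal-axis
force balance (adhesion pulling down versus Hertz repulsion and
compression pushing up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .params import ModelParameters
from .state import Cell, SimulationState

__all__ = [
    "ContactGeometry",
    "cell_cell_contact",
    "cell_substrate_contact",
    "actual_volume",
    "body_energy",
    "total_energy",
    "body_forces",
    "solve_velocities",
    "equilibrium_heights",
    "MechanicsError",
]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def _adhesion_gauge(delta, delta_m):
    """Effective cell-cell adhesion gauge g(delta) and slope g'(delta).

    The adhesion energy is -eps_cc * pi * R_eff * g(delta): linear in the
    Hertz contact zone once the contact is mature, with a quadratic onset
    over the first ``delta_m`` of overlap (bond density builds up as the
    contact zone engages).  The onset keeps the pull-off force below the
    podium protrusion force, so migrating cells can detach -- without it no
    podium could ever separate two touching bodies.
    """
    delta = np.asarray(delta, float)
    ramp = delta < delta_m
    g = np.where(ramp, delta * delta / (2.0 * delta_m), delta - delta_m / 2.0)
    gp = np.where(ramp, delta / delta_m, 1.0)
    return g, gp


class MechanicsError(RuntimeError):
    """Raised on non-convergence of the velocity solve."""


@dataclass
class ContactGeometry:
    """Geometry of one contact (cell-cell or cell-substrate)."""

    delta: float      # overlap, um
    r_contact: float  # contact-circle radius, um
    A: float          # contact area, um^2
    h_i: float        # spherical cap height on cell i, um
    h_j: float        # cap height on cell j (0 for substrate contacts), um
    a_is: float = 0.0  # substrate adhesion radius (substrate contacts only)


def cell_cell_contact(cell_i: Cell, cell_j: Cell) -> ContactGeometry:
    """Sphere-sphere contact geometry from the planar centre distance."""
    d = float(np.hypot(*(cell_j.center - cell_i.center)))
    if d == 0.0:
        raise ValueError("coincident cell centres")
    Ri, Rj = cell_i.R, cell_j.R
    if d >= Ri + Rj:
        return ContactGeometry(0.0, 0.0, 0.0, 0.0, 0.0)
    xi = (d * d - Rj * Rj + Ri * Ri) / (2.0 * d)
    rc2 = max(Ri * Ri - xi * xi, 0.0)
    return ContactGeometry(
        delta=Ri + Rj - d, r_contact=math.sqrt(rc2), A=math.pi * rc2,
        h_i=max(Ri - xi, 0.0), h_j=max(Rj - (d - xi), 0.0))


def cell_substrate_contact(cell: Cell, center_height: float) -> ContactGeometry:
    """Flattening of a sphere against the substrate plane at height z."""
    if center_height < 0:
        raise ValueError("centre height must be >= 0")
    R = cell.R
    delta = max(R - center_height, 0.0)
    a2 = max(R * R - center_height * center_height, 0.0)
    a = math.sqrt(a2)
    return ContactGeometry(delta=delta, r_contact=a, A=math.pi * a2,
                           h_i=delta, h_j=0.0, a_is=a)


def _cap_volume(h, R):
    """Spherical cap volume (pi h^2 / 3)(3R - h)."""
    return math.pi * h * h * (3.0 * R - h) / 3.0


def actual_volume(cell: Cell, contacts) -> float:
    """Sphere volume reduced by all contact caps, clipped at zero.

    ``contacts`` is an iterable of (cap_height,) contact cap heights on this
    cell, including the substrate cap.
    """
    v = _FOUR_THIRDS_PI * cell.R**3
    for h in contacts:
        v -= _cap_volume(h, cell.R)
    return max(v, 0.0)


def body_energy(cell: Cell, neighbors, params: ModelParameters,
                include_substrate: bool = True):
    """Per-cell energy decomposition (E_A, E_D, E_C) in nN*um.

    Pair terms are counted in full for this cell (the population energy in
    :func:`total_energy` counts each shared term once).
    """
    e_a = e_d = 0.0
    caps = []
    for other in neighbors:
        g = cell_cell_contact(cell, other)
        if g.delta <= 0:
            continue
        reff = cell.R * other.R / (cell.R + other.R)
        ga, _ = _adhesion_gauge(g.delta, params.adhesion_onset)
        e_a -= params.eps_cc * math.pi * reff * float(ga)
        e_d += (8.0 / 15.0) * params.e_star_cc() * math.sqrt(reff) * g.delta**2.5
        caps.append(g.h_i)
    if include_substrate:
        gs = cell_substrate_contact(cell, cell.height)
        e_a -= params.eps_cs * gs.A
        e_d += (8.0 / 15.0) * params.e_star_cs() * math.sqrt(cell.R) * gs.delta**2.5
        caps.append(gs.h_i)
    va = actual_volume(cell, caps)
    e_c = 0.5 * params.k_bulk * (va - cell.V_target)**2 / cell.V_target
    return e_a, e_d, e_c


# ----------------------------------------------------------------------
# array-level geometry used by the engine
# ----------------------------------------------------------------------

def contact_pairs(state: SimulationState):
    """Index pairs (i, j), i<j, of overlapping cell bodies."""
    if state.n < 2:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64))
    pts = np.column_stack([state.x, state.y])
    tree = cKDTree(pts)
    rmax = float(state.R.max())
    raw = tree.query_pairs(2.0 * rmax, output_type="ndarray")
    if raw.size == 0:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64))
    ii, jj = raw[:, 0], raw[:, 1]
    d = np.hypot(state.x[jj] - state.x[ii], state.y[jj] - state.y[ii])
    keep = d < state.R[ii] + state.R[jj]
    return ii[keep], jj[keep]


def _pair_geometry(d, Ri, Rj):
    d = np.maximum(d, np.abs(Ri - Rj) + 1e-9)  # guard containment corner
    xi = (d * d - Rj * Rj + Ri * Ri) / (2.0 * d)
    xj = d - xi
    rc2 = np.maximum(Ri * Ri - xi * xi, 0.0)
    hi = np.maximum(Ri - xi, 0.0)
    hj = np.maximum(Rj - xj, 0.0)
    return d, xi, xj, rc2, hi, hj


def _population_geometry(state: SimulationState):
    """All contact geometry arrays for the current configuration."""
    p = state.params
    ii, jj = contact_pairs(state)
    d = np.hypot(state.x[jj] - state.x[ii], state.y[jj] - state.y[ii])
    d, xi, xj, rc2, hi, hj = _pair_geometry(d, state.R[ii], state.R[jj])
    delta = np.maximum(state.R[ii] + state.R[jj] - d, 0.0)
    # substrate
    zs = np.minimum(state.z, state.R)
    hs = state.R - zs
    a2 = np.maximum(state.R**2 - zs**2, 0.0)
    # actual volumes
    va = _FOUR_THIRDS_PI * state.R**3
    va -= math.pi * hs * hs * (3.0 * state.R - hs) / 3.0
    np.add.at(va, ii, -np.pi * hi * hi * (3.0 * state.R[ii] - hi) / 3.0)
    np.add.at(va, jj, -np.pi * hj * hj * (3.0 * state.R[jj] - hj) / 3.0)
    va = np.maximum(va, 0.0)
    # reduced surface area: caps replaced by their planar circles
    s_red = 4.0 * math.pi * state.R**2
    s_red -= 2.0 * math.pi * state.R * hs - math.pi * a2
    np.add.at(s_red, ii, -(2.0 * math.pi * state.R[ii] * hi - math.pi * rc2))
    np.add.at(s_red, jj, -(2.0 * math.pi * state.R[jj] * hj - math.pi * rc2))
    # overlap-consumed surfaces cannot vanish: keep at least 5% of the
    # sphere surface so radius mobility stays bounded in extreme packing
    s_red = np.maximum(s_red, 0.05 * 4.0 * math.pi * state.R**2)
    return dict(ii=ii, jj=jj, d=d, xi=xi, xj=xj, rc2=rc2, hi=hi, hj=hj,
                delta=delta, hs=hs, a2=a2, va=va, s_red=s_red)


def total_energy(state: SimulationState) -> float:
    """Population body energy with each pair term counted once (nN*um)."""
    p = state.params
    g = _population_geometry(state)
    e = 0.0
    reff = state.R[g["ii"]] * state.R[g["jj"]] / (state.R[g["ii"]] + state.R[g["jj"]])
    ga, _ = _adhesion_gauge(g["delta"], p.adhesion_onset)
    e -= p.eps_cc * np.pi * (reff * ga).sum()
    e += (8.0 / 15.0) * p.e_star_cc() * (np.sqrt(reff) * g["delta"]**2.5).sum()
    e -= p.eps_cs * np.pi * g["a2"].sum()
    e += (8.0 / 15.0) * p.e_star_cs() * (np.sqrt(state.R) * g["hs"]**2.5).sum()
    e += 0.5 * p.k_bulk * ((g["va"] - state.vt)**2 / state.vt).sum()
    return float(e)


def body_forces(state: SimulationState):
    """Analytic planar and radius forces, plus a contact cache.

    Returns ``(F, F_R, cache)`` with ``F`` of shape (n, 2) in nN, ``F_R``
    of shape (n,) and ``cache`` the population geometry dict (used by the
    velocity solve and by the volume bookkeeping).
    """
    p = state.params
    g = _population_geometry(state)
    n = state.n
    F = np.zeros((n, 2))
    FR = np.zeros(n)
    cfac = p.k_bulk * (g["va"] - state.vt) / state.vt  # dE_C/dV_actual
    ii, jj = g["ii"], g["jj"]
    if ii.size:
        d, xi, xj = g["d"], g["xi"], g["xj"]
        hi, hj, delta = g["hi"], g["hj"], g["delta"]
        Ri, Rj = state.R[ii], state.R[jj]
        estar = p.e_star_cc()
        reff = Ri * Rj / (Ri + Rj)
        sq_reff = np.sqrt(reff)
        # dE/dd, u = unit vector from i to j; adhesion acts over the
        # elastic (Hertz) contact zone with a maturation onset
        ga, gslope = _adhesion_gauge(delta, p.adhesion_onset)
        dEdd = p.eps_cc * np.pi * reff * gslope
        dEdd -= (4.0 / 3.0) * estar * sq_reff * delta**1.5     # Hertz
        dEdd += cfac[ii] * np.pi * hi * (2.0 * Ri - hi) * xj / d
        dEdd += cfac[jj] * np.pi * hj * (2.0 * Rj - hj) * xi / d
        ux = (state.x[jj] - state.x[ii]) / d
        uy = (state.y[jj] - state.y[ii]) / d
        np.add.at(F[:, 0], ii, dEdd * ux)
        np.add.at(F[:, 1], ii, dEdd * uy)
        np.add.at(F[:, 0], jj, -dEdd * ux)
        np.add.at(F[:, 1], jj, -dEdd * uy)
        # radius gradients from pair terms
        d15 = delta**1.5
        d25 = delta * d15
        for (a, b, ha, hb, xa, xb, Ra, Rb) in (
                (ii, jj, hi, hj, xi, xj, Ri, Rj),
                (jj, ii, hj, hi, xj, xi, Rj, Ri)):
            dE_dR = -p.eps_cc * np.pi * (
                (Rb / (Ra + Rb))**2 * ga + reff * gslope)      # adhesion
            dE_dR += (4.0 / 3.0) * estar * sq_reff * d15       # Hertz, d(delta)/dR
            dE_dR += (8.0 / 15.0) * estar * d25 / (2.0 * sq_reff) \
                * (Rb / (Ra + Rb))**2                          # Hertz, dR_eff/dR
            # own compression: cap term pi h^2 (dcap/dR) + cap slope via h
            dva = -(np.pi * ha * ha
                    + np.pi * ha * (2.0 * Ra - ha) * (1.0 - Ra / d))
            dE_dR += cfac[a] * dva
            # neighbour compression: its cap height shifts with our radius
            dE_dR += cfac[b] * (-np.pi * hb * (2.0 * Rb - hb)) * (Ra / d)
            np.add.at(FR, a, -dE_dR)
    # substrate terms (z held fixed: quasi-static normal balance)
    hs, a2 = g["hs"], g["a2"]
    estar_s = p.e_star_cs()
    dE_dR = -p.eps_cs * 2.0 * np.pi * state.R
    dE_dR += (4.0 / 3.0) * estar_s * np.sqrt(state.R) * hs**1.5
    dE_dR += (8.0 / 15.0) * estar_s * hs**2.5 / (2.0 * np.sqrt(state.R))
    dva_s = -(np.pi * hs * hs + np.pi * hs * (2.0 * state.R - hs))
    dE_dR += cfac * dva_s
    # sphere-volume growth term of the compression energy
    dE_dR += cfac * 4.0 * np.pi * state.R**2
    FR -= dE_dR
    return F, FR, g


def solve_velocities(state: SimulationState, F, FR, cache, tractions=None):
    """Solve the coupled over-damped force balance for all cells.

    Translational system per axis:
    ``(gamma_cs A_is + gamma_v) v_i + gamma_cc sum_j A_ij (v_i - v_j) = rhs_i``
    with ``rhs`` the body force plus the podium traction sum.  The radius
    velocity is local: ``gamma_R S~_i Rdot_i = F_R,i``.
    """
    p = state.params
    n = state.n
    if n == 0:
        return np.zeros((0, 2)), np.zeros(0)
    rhs = np.array(F, dtype=float, copy=True)
    if tractions is not None:
        rhs = rhs + tractions
    diag = p.gamma_cs * np.pi * cache["a2"] + p.gamma_v
    ii, jj = cache["ii"], cache["jj"]
    aij = np.pi * cache["rc2"]
    if ii.size == 0:
        v = rhs / diag[:, None]
    else:
        np.add.at(diag, ii, p.gamma_cc * aij)
        np.add.at(diag, jj, p.gamma_cc * aij)
        rows = np.concatenate([np.arange(n), ii, jj])
        cols = np.concatenate([np.arange(n), jj, ii])
        vals = np.concatenate([diag, -p.gamma_cc * aij, -p.gamma_cc * aij])
        M = csc_matrix((vals, (rows, cols)), shape=(n, n))
        try:
            v = splu(M).solve(rhs)
        except RuntimeError as exc:  # pragma: no cover - SPD by construction
            raise MechanicsError(f"velocity solve failed: {exc}") from exc
        res = np.abs(M @ v - rhs).max()
        scale = max(np.abs(rhs).max(), 1e-12)
        if not np.isfinite(res) or res > 1e-8 * scale:
            raise MechanicsError(
                f"velocity solve failed to converge (residual {res:.3e})")
    vR = FR / (p.gamma_r * cache["s_red"])
    return v, vR


def equilibrium_heights(params: ModelParameters, R, vt, other_cap_vol,
                        tol: float = 1e-6):
    """Quasi-static centre heights from the normal force balance.

    Solves ``dE/dz = 0`` per cell by vectorised bisection on [0, R], where
    the energy combines substrate adhesion (pulling the centre down),
    substrate Hertz repulsion and the compression energy of the actual
    volume (``other_cap_vol`` = volume already removed by cell-cell caps).
    """
    R = np.asarray(R, float)
    vt = np.asarray(vt, float)
    other = np.asarray(other_cap_vol, float)
    estar = params.e_star_cs()

    def grad(z):
        h = R - z
        v = _FOUR_THIRDS_PI * R**3 - other \
            - math.pi * h * h * (3.0 * R - h) / 3.0
        g = 2.0 * math.pi * params.eps_cs * z
        g -= (4.0 / 3.0) * estar * np.sqrt(R) * h**1.5
        g += params.k_bulk * (np.maximum(v, 0.0) - vt) / vt \
            * math.pi * h * (2.0 * R - h)
        return g

    lo = np.full_like(R, 1e-9)
    hi = R.copy()
    glo = grad(lo)
    # adhesion never dominates at z = R (grad > 0 there); if the gradient is
    # already positive at z ~ 0 the balance sits at full flattening.
    flat = glo > 0
    for _ in range(26):
        mid = 0.5 * (lo + hi)
        gm = grad(mid)
        neg = gm < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
        if np.all(hi - lo < tol):
            break
    z = 0.5 * (lo + hi)
    return np.where(flat, 1e-9, z)
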