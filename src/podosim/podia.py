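"""Podium life cycle and single-cell closed forms.

A podium is born at a random angle with length equal to half the adhesion
radius, elongates under a constant protrusion force F_p at its tip against
podium-substrate friction gamma_p while a harmonic spring k*L builds
traction between tip and body, is stochastically inactivated (protrusion
force permanently off), retracts under the spring, and is eliminated once
it hides below the cell body (L < adhesion radius).

Generation and inactivation are driven by two random processes: a Poisson
"number-of-podia" update stream at rate lambda_np (about one expected
event per minute) whose attempts are accepted with probabilities that pull
the active count towards the regulated offset n_off, and an independent
inactivation rate r_ind.  The two inactivation channels are OR-ed.

New podium angles are drawn by rejection sampling designed to avoid
overlap with existing podia; the rejection probability for each angular
neighbour is exp(-N_p |dtheta| / c_a) with N_p the current total podium
count and c_a = 3.0 rad, the two sides OR-ed.  For cells holding two
podia this reproduces the experimentally observed outgrowth-angle
distribution with its mode near 70 degrees.
"""

from __future__ import annotations

import math
from typing import Sequence, Tuple

import numpy as np

from .params import ModelParameters
from .state import MAX_PODIA, Cell, Podium

__all__ = [
    "generation_probability",
    "lambda_inactivation_probability",
    "sample_podium_angle",
    "maybe_generate_podium",
    "maybe_inactivate_podia",
    "step_podium_tips",
    "eliminate_retracted",
    "single_cell_equilibrium",
]

_TWO_PI = 2.0 * math.pi
_MAX_REJECTIONS = 100


def generation_probability(n_active, n_off, scale: float = 0.05):
    """Acceptance probability of a generation attempt.

    Clamped linear in the podium deficit below the regulated offset,
    shifted by one half and multiplied by a small acceptance scale
    (default 0.05 per update).  The half shift makes half-integer offsets
    (3.5 low density, 2.5 high) hold exactly floor(n_off) active podia
    with zero churn at the regime count, so resting spindles stretch
    their podia to the 25 um maximum.  The scale sets the regeneration
    time of a lost podium to tens of minutes, which is what makes cells
    migrate: after a random inactivation the remaining asymmetric podium
    configuration pulls the body at roughly the single-podium equilibrium
    speed until the complement is restored.
    """
    return np.clip(scale * (np.asarray(n_off, float)
                            - np.asarray(n_active, float) - 0.5),
                   0.0, 1.0)[()]


def lambda_inactivation_probability(n_active, n_off):
    """Podium-count-related inactivation probability on a lambda update.

    Clamped linear in the excess of the active count over the offset: a
    podium in excess of the regime count (half-integer offsets put the
    stable count at floor(n_off)) is shed within a few updates.
    """
    return np.clip(np.asarray(n_active, float) - np.asarray(n_off, float),
                   0.0, 1.0)[()]


def _rejection_probability(prop: float, angles: np.ndarray, c_a: float) -> float:
    """OR-combined rejection probability against the nearest angular
    neighbours left and right of a proposal."""
    n_p = angles.size
    if n_p == 0:
        return 0.0
    d = np.angle(np.exp(1j * (angles - prop)))
    left = d[d <= 0]
    right = d[d > 0]
    probs = []
    if left.size:
        probs.append(math.exp(-n_p * abs(left.max()) / c_a))
    if right.size:
        probs.append(math.exp(-n_p * right.min() / c_a))
    p = 0.0
    for q in probs:
        p = p + q - p * q
    return p


def sample_podium_angle(existing_angles: Sequence[float],
                        params: ModelParameters, rng) -> float:
    """Draw a new podium direction avoiding existing podia.

    Uniform proposals on [0, 2pi) are rejected with the OR-combined
    exponential rejection probability; after 100 rejections the proposal
    with the lowest rejection probability seen so far is accepted.
    """
    angles = np.asarray(existing_angles, dtype=float)
    if angles.size == 0:
        return float(rng.uniform(0.0, _TWO_PI))
    best, best_p = 0.0, 2.0
    for _ in range(_MAX_REJECTIONS):
        prop = float(rng.uniform(0.0, _TWO_PI))
        p = _rejection_probability(prop, angles, params.c_a)
        if rng.uniform() >= p:
            return prop
        if p < best_p:
            best, best_p = prop, p
    return best


def maybe_generate_podium(cell: Cell, params: ModelParameters, dt: float,
                          rng) -> Cell:
    """One generation update: Poisson lambda event, clamped acceptance.

    Podia are suppressed in the pre-division phases 3 and 4.  A freshly
    generated podium is active with length a_is/2 (tip at the body edge).
    """
    if cell.phase in (3, 4) or len(cell.podia) >= MAX_PODIA:
        return cell
    if rng.uniform() >= -math.expm1(-params.lambda_np * dt):
        return cell
    n_off = cell.reg.n_off if cell.reg is not None else params.n_off_lo
    p_gen = generation_probability(cell.n_active(), n_off,
                                   params.gen_accept_scale)
    if rng.uniform() < p_gen:
        if not cell.podia and cell.division_axis is not None:
            # newborn daughters elongate along their outward division axis
            angle = cell.division_axis
            cell.division_axis = None
        else:
            angle = sample_podium_angle([p.angle for p in cell.podia],
                                        params, rng)
        cell.podia.append(Podium(angle=angle, length=cell.adhesion_radius / 2.0))
    return cell


def maybe_inactivate_podia(cell: Cell, params: ModelParameters, dt: float,
                           rng) -> Cell:
    """One inactivation update; both channels OR-ed per podium."""
    if not cell.podia:
        return cell
    n_off = cell.reg.n_off if cell.reg is not None else params.n_off_lo
    r_ind = cell.reg.r_ind if cell.reg is not None else params.r_ind_lo
    lam_event = rng.uniform() < -math.expm1(-params.lambda_np * dt)
    p_r = -math.expm1(-r_ind * dt)
    p_lam = (lambda_inactivation_probability(cell.n_active(), n_off)
             if lam_event else 0.0)
    p = p_lam + p_r - p_lam * p_r
    for podium in cell.podia:
        if not podium.active:
            continue
        if p > 0 and rng.uniform() < p:
            podium.active = False
    return cell


def step_podium_tips(cell: Cell, params: ModelParameters, dt: float) -> Cell:
    """Advance every tip along its axis: gamma_p dL/dt = F_p*active - k L.

    The tip equation is linear, so the update uses the exact exponential
    propagator towards the fixed point F_p/k (active) or 0 (retracting);
    this is unconditionally stable and step-size exact.
    """
    decay = math.exp(-params.k_spring * dt / params.gamma_p)
    for podium in cell.podia:
        l_inf = params.f_p / params.k_spring if podium.active else 0.0
        podium.length = max(l_inf + (podium.length - l_inf) * decay, 0.0)
    return cell


def eliminate_retracted(cell: Cell) -> Cell:
    """Remove inactive podia hidden below the body (L < adhesion radius)."""
    a = cell.adhesion_radius
    cell.podia = [p for p in cell.podia if p.active or p.length >= a]
    return cell


def single_cell_equilibrium(params: ModelParameters, n_active: int,
                            n_trailing: int) -> Tuple[float, Tuple[float, ...]]:
    """Closed-form steady state of the coupled tip/centre system.

    Supported configurations: a resting cell (0 active, 0 trailing), one
    active podium, and one active plus one trailing (inactive, opposite)
    podium.  Returns (speed um/min, podium lengths um), active first.
    """
    from .mechanics import equilibrium_heights

    if (n_active, n_trailing) not in ((0, 0), (1, 0), (1, 1)):
        raise ValueError("unsupported configuration for the closed forms")
    z = float(equilibrium_heights(params, np.array([params.r0]),
                                  np.array([params.v0]), np.array([0.0]))[0])
    a2 = max(params.r0**2 - z**2, 0.0)
    gamma_b = params.gamma_cs * math.pi * a2 + params.gamma_v
    fp, k, gp = params.f_p, params.k_spring, params.gamma_p
    if (n_active, n_trailing) == (0, 0):
        return 0.0, ()
    if (n_active, n_trailing) == (1, 0):
        v = fp / (gp + gamma_b)
        return v, (gamma_b * fp / (k * (gp + gamma_b)),)
    v = fp / (2.0 * gp + gamma_b)
    l_active = fp * (gp + gamma_b) / (k * (2.0 * gp + gamma_b))
    l_trail = gp * fp / (k * (2.0 * gp + gamma_b))
    return v, (l_active, l_trail)
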