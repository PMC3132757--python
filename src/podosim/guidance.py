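"""Contact guidance: pairwise podium overlap resolution and groove alignment.

Cell-cell alignment is produced by a heuristic, basically pairwise rule
set: after every podium has been advanced by its own dynamics, podium axes
(mid-lines from the cone base at the cell centre to the tip centre,
inflated by the moving tip radius) are checked for intersection with the
podia and bodies of neighbouring cells.  An overlapping podium is rotated
about its base by the minimal angle that clears the obstacle, with its
length preserved.  Which podium of a pair moves is decided by a global
precedence scheme:

* small overlaps (mid-lines do not intersect): the intersecting podium
  moves off the resting cell (cases C1 podium-podium, C2 podium-body);
* large overlaps (mid-lines intersect): the podium whose tip is closer to
  the intersection point moves; head-on ties move the shorter podium, and
  exact ties fall back to (cell id, podium index) order;
* a moved podium inherits precedence one above the resting podium, and a
  podium with higher precedence always moves; precedence resets to one
  when a podium is clear;
* multiple intersections with the same cell apply only the 'nearest'
  move (shortest distance from the cell centre); intersections with
  several distinct cells are resolved one at a time in the fixed record
  order, re-verifying each overlap before moving;
* switched-off podia are never shifted.

Microgrooves behave like podia that are never moved, except that the
alignment fires with probability ``p_groove`` per podium per step and is
skipped when the tip centre already lies inside the groove (letting cells
climb and cross grooves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .geometry import capsule_distance, seg_seg_closest, segments_cross
from .params import ModelParameters
from .state import MAX_PODIA, Cell, SimulationState

__all__ = ["OverlapReport", "detect_overlap", "resolve_overlaps",
           "align_to_grooves"]

_TWO_PI = 2.0 * math.pi
_CLEAR_TOL = 1e-3  # rad, bisection tolerance for the clearing rotation


@dataclass
class OverlapReport:
    kind: str                       # 'none' | 'small' | 'large'
    case: Optional[str] = None      # 'C1' | 'C2' | 'C3'
    location: Optional[np.ndarray] = None


def _wrap(angle: float) -> float:
    """Wrap to (-pi, pi]."""
    return math.atan2(math.sin(angle), math.cos(angle))


def _axis(cell_x, cell_y, a, angle, length):
    tipd = a / 2.0 + length
    return (cell_x, cell_y,
            cell_x + tipd * math.cos(angle), cell_y + tipd * math.sin(angle))


def detect_overlap(podium, owner: Cell, other: Cell,
                   params: ModelParameters) -> OverlapReport:
    """Classify the overlap of one podium's mid-line with another cell.

    Only the axis of the moving podium is tested (inflated by its tip
    radius); the other cell contributes its body disc and full podium
    cones.  'small' means no mid-line crossing; the case distinguishes
    podium-podium (C1), podium-body (C2) and large overlaps (C3).
    """
    rt = owner.tip_radius(params)
    ax = _axis(owner.center[0], owner.center[1], owner.adhesion_radius,
               podium.angle, podium.length)
    bx, by = other.center
    ab, rtb = other.adhesion_radius, other.tip_radius(params)
    best = OverlapReport("none")
    best_d = np.inf
    # body disc
    d = capsule_distance(ax[0], ax[1], ax[2], ax[3], 0.0, 0.0,
                         bx, by, bx, by, ab, ab)
    if d < rt and d < best_d:
        tau2 = (ax[0] - bx)**2 + (ax[1] - by)**2 - (ab + rt)**2
        ell2 = (ax[2] - ax[0])**2 + (ax[3] - ax[1])**2
        case = "C2" if ell2 <= max(tau2, 0.0) else "C3"
        kind = "small" if case == "C2" else "large"
        best = OverlapReport(kind, case, np.array([bx, by]))
        best_d = d
    for q in other.podia:
        qx = _axis(bx, by, ab, q.angle, q.length)
        d = capsule_distance(ax[0], ax[1], ax[2], ax[3], 0.0, 0.0,
                             qx[0], qx[1], qx[2], qx[3], ab, rtb)
        if d < rt and d < best_d:
            crossing = segments_cross(ax[0], ax[1], ax[2], ax[3],
                                      qx[0], qx[1], qx[2], qx[3])
            kind = "large" if crossing else "small"
            case = "C3" if crossing else "C1"
            loc = _cross_point(ax, qx) if crossing else None
            best = OverlapReport(kind, case, loc)
            best_d = d
    return best


def _cross_point(p, q):
    ux, uy = p[2] - p[0], p[3] - p[1]
    vx, vy = q[2] - q[0], q[3] - q[1]
    den = ux * vy - uy * vx
    if abs(den) < 1e-12:
        return np.array([(p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0])
    t = ((q[0] - p[0]) * vy - (q[1] - p[1]) * vx) / den
    return np.array([p[0] + t * ux, p[1] + t * uy])


# ----------------------------------------------------------------------
# detection kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _detect_kernel(ci, cj, X, Y, A, RT, PANG, PLEN, PON, PACT, REACH):
    """Overlap/crossing bitmasks for moving podia of candidate cell pairs.

    For each candidate pair (both directions) and each moving podium, bit b
    of ``ov`` marks an overlap with resting primitive b (0 = body, 1+q =
    podium q) and bit b of ``crs`` a mid-line crossing.
    """
    ncand = ci.shape[0]
    ov = np.zeros((2 * ncand, MAX_PODIA), dtype=np.uint16)
    crs = np.zeros((2 * ncand, MAX_PODIA), dtype=np.uint16)
    for k in range(2 * ncand):
        if k < ncand:
            a_i, b_i = ci[k], cj[k]
        else:
            a_i, b_i = cj[k - ncand], ci[k - ncand]
        axc, ayc = X[a_i], Y[a_i]
        bxc, byc = X[b_i], Y[b_i]
        rt = RT[a_i]
        ab = A[b_i]
        rtb = RT[b_i]
        dcc = math.sqrt((axc - bxc)**2 + (ayc - byc)**2)
        for p in range(MAX_PODIA):
            # switched-off podia are never shifted, so they never act as
            # the moving axis; the mirrored direction still detects them
            # as obstacles
            if not PON[a_i, p] or not PACT[a_i, p]:
                continue
            tipd = A[a_i] / 2.0 + PLEN[a_i, p]
            if dcc - tipd - REACH[b_i] - rt > 0.0:
                continue
            tx = axc + tipd * math.cos(PANG[a_i, p])
            ty = ayc + tipd * math.sin(PANG[a_i, p])
            mask = np.uint16(0)
            cmask = np.uint16(0)
            # body: point-to-segment distance is exact here; it also bounds
            # every other primitive of b (their reach from b's centre)
            s0, _, segd = seg_seg_closest(axc, ayc, tx, ty,
                                          bxc, byc, bxc, byc)
            if segd - REACH[b_i] - rt > 0.0:
                continue
            if segd - ab < rt:
                mask |= np.uint16(1)
            for q in range(MAX_PODIA):
                if not PON[b_i, q]:
                    continue
                tqd = ab / 2.0 + PLEN[b_i, q]
                tqx = bxc + tqd * math.cos(PANG[b_i, q])
                tqy = byc + tqd * math.sin(PANG[b_i, q])
                # cheap axis-axis bounds before the exact capsule distance
                _, tq, segd = seg_seg_closest(axc, ayc, tx, ty,
                                              bxc, byc, tqx, tqy)
                if segd - ab < rt:
                    hit = True   # radius lower bound ab is the cone maximum
                    if segd - (ab + tq * (rtb - ab)) >= rt:
                        hit = capsule_distance(
                            axc, ayc, tx, ty, 0.0, 0.0,
                            bxc, byc, tqx, tqy, ab, rtb) < rt
                    if hit:
                        mask |= np.uint16(1 << (q + 1))
                        if segments_cross(axc, ayc, tx, ty,
                                          bxc, byc, tqx, tqy):
                            cmask |= np.uint16(1 << (q + 1))
            ov[k, p] = mask
            crs[k, p] = cmask
    return ov, crs


# ----------------------------------------------------------------------
# clearing rotation and the sequential resolution pass (numba)
# ----------------------------------------------------------------------

@njit(cache=True)
def _wrap_nb(a):
    return math.atan2(math.sin(a), math.cos(a))


@njit(cache=True)
def _clear_rotation_nb(bx0, by0, theta, ell, rt_m,
                       c1x, c1y, rho1, c2x, c2y, rho2, ncirc,
                       qx0, qy0, qx1, qy1, rb0, rb1):
    """Minimal-rotation direction clearing the resting primitive.

    The primitive's silhouette from the podium base is bounded by its two
    end discs; the blocked angular interval of each disc has a closed form
    (tangent wedge, or the tip-reach wedge for short podia).  The nearest
    interval edge is verified against the exact capsule distance and, if
    the analytic wedge underestimates (the hull's straight flanks), refined
    by widening plus bisection to 1e-3 rad.  Returns NaN when no clearing
    rotation exists (base engulfed or fully blocked).
    """
    los = np.empty(2)
    his = np.empty(2)
    nint = 0
    for ci in range(ncirc):
        cx = c1x if ci == 0 else c2x
        cy = c1y if ci == 0 else c2y
        rho = rho1 if ci == 0 else rho2
        wx, wy = cx - bx0, cy - by0
        wn = math.hypot(wx, wy)
        if wn <= rho:
            return np.nan
        if ell + rho < wn:
            continue
        psi = math.atan2(wy, wx)
        tau = math.sqrt(wn * wn - rho * rho)
        if ell >= tau:
            half = math.asin(rho / wn)
        else:
            c = (wn * wn + ell * ell - rho * rho) / (2.0 * ell * wn)
            if c >= 1.0:
                continue
            if c < -1.0:
                c = -1.0
            half = math.acos(c)
        los[nint] = psi - half
        his[nint] = psi + half
        nint += 1
    if nint == 0:
        cand = theta
    else:
        cands = np.empty(4)
        nc = 0
        for k in range(nint):
            cands[nc] = los[k] - _CLEAR_TOL
            nc += 1
            cands[nc] = his[k] + _CLEAR_TOL
            nc += 1
        for i in range(1, nc):
            key = cands[i]
            kd = abs(_wrap_nb(key - theta))
            j = i - 1
            while j >= 0 and abs(_wrap_nb(cands[j] - theta)) > kd:
                cands[j + 1] = cands[j]
                j -= 1
            cands[j + 1] = key
        cand = np.nan
        for i in range(nc):
            ok = True
            for k in range(nint):
                mid = 0.5 * (los[k] + his[k])
                half = 0.5 * (his[k] - los[k])
                if abs(_wrap_nb(cands[i] - mid)) < half:
                    ok = False
                    break
            if ok:
                cand = cands[i]
                break
        if math.isnan(cand):
            return np.nan
    tx = bx0 + ell * math.cos(cand)
    ty = by0 + ell * math.sin(cand)
    if capsule_distance(bx0, by0, tx, ty, 0.0, 0.0,
                        qx0, qy0, qx1, qy1, rb0, rb1) >= rt_m:
        return cand % _TWO_PI
    direction = 1.0 if _wrap_nb(cand - theta) >= 0 else -1.0
    hi = cand
    found = False
    for _ in range(8):
        hi += direction * 0.15
        tx = bx0 + ell * math.cos(hi)
        ty = by0 + ell * math.sin(hi)
        if capsule_distance(bx0, by0, tx, ty, 0.0, 0.0,
                            qx0, qy0, qx1, qy1, rb0, rb1) >= rt_m:
            found = True
            break
    if not found:
        return np.nan
    lo = cand
    while abs(hi - lo) > _CLEAR_TOL:
        mid = 0.5 * (lo + hi)
        tx = bx0 + ell * math.cos(mid)
        ty = by0 + ell * math.sin(mid)
        if capsule_distance(bx0, by0, tx, ty, 0.0, 0.0,
                            qx0, qy0, qx1, qy1, rb0, rb1) >= rt_m:
            hi = mid
        else:
            lo = mid
    return hi % _TWO_PI


@njit(cache=True)
def _records_kernel(ii, jj, ov, crs, X, Y, A, RT, PANG, PLEN, involved):
    """Per-overlap records from the detection masks.

    One record per (moving podium, resting cell): the 'nearest' resting
    primitive (shortest distance from the moving cell centre to the hit
    point), per the multiple-intersections-with-one-cell rule.
    """
    ncand = ii.shape[0]
    nz = 0
    for k in range(ov.shape[0]):
        for p in range(MAX_PODIA):
            if ov[k, p] != 0:
                nz += 1
    ra = np.empty(nz, np.int64)
    rp = np.empty(nz, np.int64)
    rb = np.empty(nz, np.int64)
    rq = np.empty(nz, np.int64)
    rl = np.zeros(nz, np.uint8)
    rx = np.empty(nz)
    ry = np.empty(nz)
    idx = 0
    for k in range(ov.shape[0]):
        if k < ncand:
            a_i, b_i = ii[k], jj[k]
        else:
            a_i, b_i = jj[k - ncand], ii[k - ncand]
        for p in range(MAX_PODIA):
            mask = ov[k, p]
            if mask == 0:
                continue
            involved[a_i, p] = True
            cmask = crs[k, p]
            ell = A[a_i] / 2.0 + PLEN[a_i, p]
            ang = PANG[a_i, p]
            tx = X[a_i] + ell * math.cos(ang)
            ty = Y[a_i] + ell * math.sin(ang)
            best_d = 1e30
            for b in range(MAX_PODIA + 1):
                if not (mask >> b) & 1:
                    continue
                res_pod = b - 1
                if res_pod >= 0:
                    involved[b_i, res_pod] = True
                if res_pod < 0:
                    qx0 = X[b_i]
                    qy0 = Y[b_i]
                    qx1 = qx0
                    qy1 = qy0
                else:
                    tqd = A[b_i] / 2.0 + PLEN[b_i, res_pod]
                    aq = PANG[b_i, res_pod]
                    qx0 = X[b_i]
                    qy0 = Y[b_i]
                    qx1 = qx0 + tqd * math.cos(aq)
                    qy1 = qy0 + tqd * math.sin(aq)
                large = res_pod >= 0 and ((cmask >> b) & 1) == 1
                if large and segments_cross(X[a_i], Y[a_i], tx, ty,
                                            qx0, qy0, qx1, qy1):
                    ux, uy = tx - X[a_i], ty - Y[a_i]
                    vx, vy = qx1 - qx0, qy1 - qy0
                    den = ux * vy - uy * vx
                    if abs(den) < 1e-12:
                        px = 0.5 * (X[a_i] + qx0)
                        py = 0.5 * (Y[a_i] + qy0)
                    else:
                        t = ((qx0 - X[a_i]) * vy - (qy0 - Y[a_i]) * vx) / den
                        px = X[a_i] + t * ux
                        py = Y[a_i] + t * uy
                else:
                    sv, _, _ = seg_seg_closest(X[a_i], Y[a_i], tx, ty,
                                               qx0, qy0, qx1, qy1)
                    px = X[a_i] + sv * (tx - X[a_i])
                    py = Y[a_i] + sv * (ty - Y[a_i])
                dist = math.hypot(px - X[a_i], py - Y[a_i])
                if dist < best_d:
                    best_d = dist
                    ra[idx] = a_i
                    rp[idx] = p
                    rb[idx] = b_i
                    rq[idx] = res_pod
                    rl[idx] = 1 if large else 0
                    rx[idx] = px
                    ry[idx] = py
            idx += 1
    return (ra[:idx], rp[:idx], rb[:idx], rq[:idx], rl[:idx],
            rx[:idx], ry[:idx])


@njit(cache=True)
def _apply_kernel(order, ra, rp, rb, rq, rl, rx, ry, stalled,
                  X, Y, A, RT, PANG, PLEN, PON, PACT, PPREC, IDS):
    """Sequential application of the precedence scheme, in fixed order."""
    for oi in range(order.shape[0]):
        r = order[oi]
        a_i, p, b_i, q = ra[r], rp[r], rb[r], rq[r]
        if not PON[a_i, p] or (q >= 0 and not PON[b_i, q]):
            continue
        # re-verify: earlier moves may have cleared this overlap
        ell = A[a_i] / 2.0 + PLEN[a_i, p]
        ang = PANG[a_i, p]
        tx = X[a_i] + ell * math.cos(ang)
        ty = Y[a_i] + ell * math.sin(ang)
        if q < 0:
            qx0, qy0 = X[b_i], Y[b_i]
            qx1, qy1 = qx0, qy0
            rb0 = rb1 = A[b_i]
        else:
            tqd = A[b_i] / 2.0 + PLEN[b_i, q]
            aq = PANG[b_i, q]
            qx0, qy0 = X[b_i], Y[b_i]
            qx1 = qx0 + tqd * math.cos(aq)
            qy1 = qy0 + tqd * math.sin(aq)
            rb0, rb1 = A[b_i], RT[b_i]
        if capsule_distance(X[a_i], Y[a_i], tx, ty, 0.0, 0.0,
                            qx0, qy0, qx1, qy1, rb0, rb1) >= RT[a_i]:
            continue
        if q < 0:
            # podium-body: the podium always moves off the body
            if not PACT[a_i, p] or stalled[a_i, p]:
                continue
            newang = _clear_rotation_nb(
                X[a_i], Y[a_i], PANG[a_i, p], ell, RT[a_i],
                X[b_i], Y[b_i], A[b_i] + RT[a_i], 0.0, 0.0, 0.0, 1,
                qx0, qy0, qx1, qy1, rb0, rb1)
            if not math.isnan(newang):
                PANG[a_i, p] = newang
            continue
        # podium-podium: precedence, then the tip-distance / length /
        # (cell id, podium index) cascade for large overlaps
        m_c, m_p, r_c, r_p = a_i, p, b_i, q
        swap = False
        if PPREC[b_i, q] > PPREC[a_i, p]:
            swap = True
        elif PPREC[b_i, q] == PPREC[a_i, p] and rl[r] == 1:
            ta_x = tx
            ta_y = ty
            eb = A[b_i] / 2.0 + PLEN[b_i, q]
            tb_x = X[b_i] + eb * math.cos(PANG[b_i, q])
            tb_y = Y[b_i] + eb * math.sin(PANG[b_i, q])
            da = math.hypot(ta_x - rx[r], ta_y - ry[r])
            db = math.hypot(tb_x - rx[r], tb_y - ry[r])
            if db < da - 1e-9:
                swap = True
            elif abs(db - da) <= 1e-9:
                la, lb = PLEN[a_i, p], PLEN[b_i, q]
                if lb < la - 1e-9:
                    swap = True
                elif abs(lb - la) <= 1e-9 and (
                        IDS[b_i] < IDS[a_i]
                        or (IDS[b_i] == IDS[a_i] and q < p)):
                    swap = True
        if swap:
            m_c, m_p, r_c, r_p = b_i, q, a_i, p
        # switched-off podia are never shifted
        if not PACT[m_c, m_p]:
            if PACT[r_c, r_p]:
                m_c, m_p, r_c, r_p = r_c, r_p, m_c, m_p
            else:
                continue
        if stalled[m_c, m_p]:
            continue
        ellm = A[m_c] / 2.0 + PLEN[m_c, m_p]
        tqd = A[r_c] / 2.0 + PLEN[r_c, r_p]
        aq = PANG[r_c, r_p]
        qx0, qy0 = X[r_c], Y[r_c]
        qx1 = qx0 + tqd * math.cos(aq)
        qy1 = qy0 + tqd * math.sin(aq)
        newang = _clear_rotation_nb(
            X[m_c], Y[m_c], PANG[m_c, m_p], ellm, RT[m_c],
            X[r_c], Y[r_c], A[r_c] + RT[m_c],
            qx1, qy1, RT[r_c] + RT[m_c], 2,
            qx0, qy0, qx1, qy1, A[r_c], RT[r_c])
        if not math.isnan(newang):
            PANG[m_c, m_p] = newang
            PPREC[m_c, m_p] = PPREC[r_c, r_p] + 1


# ----------------------------------------------------------------------
# full resolution pass
# ----------------------------------------------------------------------

def _candidate_pairs(state: SimulationState):
    if state.n < 2:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64))
    a = state.a
    rt = state.tip_r
    ext = a[:, None] / 2.0 + np.where(state.p_on, state.p_len, 0.0) \
        + rt[:, None]
    reach = np.maximum(a, ext.max(axis=1))
    tree = cKDTree(np.column_stack([state.x, state.y]))
    raw = tree.query_pairs(2.0 * float(reach.max()) + 1.0,
                           output_type="ndarray")
    if raw.size == 0:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64))
    ii, jj = raw[:, 0].astype(np.int64), raw[:, 1].astype(np.int64)
    d = np.hypot(state.x[jj] - state.x[ii], state.y[jj] - state.y[ii])
    keep = d < reach[ii] + reach[jj] + rt[ii] + rt[jj]
    return ii[keep], jj[keep]


def resolve_overlaps(state: SimulationState, pairs=None) -> SimulationState:
    """One global guidance pass over all overlapping podium pairs."""
    ii, jj = _candidate_pairs(state) if pairs is None else pairs
    involved = np.zeros((state.n, MAX_PODIA), dtype=np.bool_)
    if ii.size:
        av = state.a
        rtv = state.tip_r
        reach = av / 2.0 + np.where(state.p_on, state.p_len, 0.0).max(axis=1) \
            + rtv
        ov, crs = _detect_kernel(ii, jj, state.x, state.y, av, rtv,
                                 state.p_ang, state.p_len, state.p_on,
                                 state.p_act, reach)
        ra, rp, rb, rq, rl, rx, ry = _records_kernel(
            ii, jj, ov, crs, state.x, state.y, av, rtv,
            state.p_ang, state.p_len, involved)
        if ra.size:
            # fixed processing order: (cell id, podium index) of the mover,
            # then of the resting side
            order = np.lexsort((rq, state.ids[rb], rp, state.ids[ra]))
            # conflicting multi-cell intersections are NOT stalled: the
            # records are applied one obstacle at a time in fixed order
            # with re-verification.  Stalling multiply-conflicted podia
            # (or their owner cells) freezes confluent cultures entirely
            # and no nematic alignment can develop.
            stalled = np.zeros((state.n, MAX_PODIA), dtype=np.bool_)
            _apply_kernel(order, ra, rp, rb, rq, rl, rx, ry, stalled,
                          state.x, state.y, av, rtv, state.p_ang,
                          state.p_len, state.p_on, state.p_act,
                          state.p_prec, state.ids)
    # precedence resets for podia clear of any intersection
    state.p_prec[state.p_on & ~involved] = 1
    return state


# ----------------------------------------------------------------------
# microgroove alignment
# ----------------------------------------------------------------------

def align_to_grooves(state: SimulationState, rng=None) -> SimulationState:
    """Stochastic podium-to-groove alignment (grooves never move)."""
    pat = state.substrate
    if not pat.has_grooves or state.params.p_groove <= 0 or state.n == 0:
        return state
    rng = rng if rng is not None else state.rng
    fire = rng.random((state.n, MAX_PODIA)) < state.params.p_groove
    fire &= state.p_on
    idx = np.argwhere(fire)
    av = state.a
    for c, p in idx:
        _align_one(state, av, int(c), int(p))
    return state


def _align_one(state, av, c, p):
    base_x, base_y = state.x[c], state.y[c]
    ell = av[c] / 2.0 + state.p_len[c, p]
    ang = state.p_ang[c, p]
    tx, ty = base_x + ell * math.cos(ang), base_y + ell * math.sin(ang)
    best = None
    best_d = np.inf
    for g in state.substrate.grooves:
        (lon0, lat0) = [float(v) for v in g.local_coords(base_x, base_y)]
        (lon1, lat1) = [float(v) for v in g.local_coords(tx, ty)]
        # tip centre already inside ('climbed') -> skip this groove
        if abs(lat1) <= g.half_width and abs(lon1) <= g.half_length:
            continue
        hit = _edge_crossing(lon0, lat0, lon1, lat1, g.half_width,
                             g.half_length)
        if hit is not None and hit < best_d:
            best, best_d = g, hit
    if best is not None:
        delta = _wrap(best.angle - ang)
        target = best.angle if abs(delta) <= math.pi / 2.0 else best.angle + math.pi
        state.p_ang[c, p] = target % _TWO_PI


def _edge_crossing(lon0, lat0, lon1, lat1, hw, hl):
    """Arc-length position (from the base) of the first crossing of a
    groove edge line by the segment, or None."""
    hits = []
    dlat = lat1 - lat0
    dlon = lon1 - lon0
    for edge in (hw, -hw):
        if abs(dlat) < 1e-12:
            continue
        t = (edge - lat0) / dlat
        if 0.0 <= t <= 1.0 and abs(lon0 + t * dlon) <= hl:
            hits.append(t)
    if not hits:
        return None
    t = min(hits)
    return t * math.hypot(dlon, dlat)
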