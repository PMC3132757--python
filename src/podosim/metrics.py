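"""Spatial-organisation statistics of simulated (or segmented) populations.

The cell direction is the consensus orientation of its podia: the axis
angle phi in [0, pi) maximising sum_m |cos(phi - theta_m)| over the
podium directions theta_m.  Pairwise nematic alignment is quantified by

    S(d) = < cos(2 * dphi) >_{pairs at distance d}

which is 1 for perfectly aligned and 0 for disordered populations, and
S* averages S(d) over centre distances up to 50 um (unweighted over
occupied 5-um bins).  Population spread is summarised by the mean radial
position relative to the culture centre and by the y-to-x aspect ratio.
The kinetic exponent beta(t) is the local log-log slope of the mean
squared displacement of single-cell tracks.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "consensus_orientation",
    "consensus_orientation_angles",
    "order_parameter_profile",
    "order_parameter_star",
    "mean_population_radius",
    "aspect_ratio",
    "mean_podium_length",
    "msd_kinetic_exponent",
    "filter_frame",
    "population_metrics",
]

_DEFAULT_BIN = 5.0
_DEFAULT_RANGE = 50.0


def consensus_orientation_angles(angles) -> float:
    """Exact argmax of sum |cos(phi - theta_m)| over phi in [0, pi).

    The objective is piecewise sinusoidal with breakpoints at
    theta_m + pi/2 (mod pi); on each smooth piece it equals
    A cos(phi) + B sin(phi) for fixed signs, whose interior stationary
    point is atan2(B, A).  All breakpoints and stationary points are
    evaluated and ties resolved towards the smallest angle.
    """
    th = np.asarray(angles, dtype=float)
    if th.size == 0:
        raise ValueError("consensus orientation requires at least one podium")
    if th.size == 1:
        return float(th[0] % math.pi)
    breaks = np.unique((th + math.pi / 2.0) % math.pi)
    cands = list(breaks)
    edges = np.concatenate([breaks, [breaks[0] + math.pi]])
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        signs = np.sign(np.cos(mid - th))
        a = float((signs * np.cos(th)).sum())
        b = float((signs * np.sin(th)).sum())
        # the true argmax is either a breakpoint or the stationary point of
        # its piece; evaluating a superset of candidates is harmless
        cands.append(math.atan2(b, a) % math.pi)
    cands = np.asarray(sorted(set(round(c % math.pi, 15) for c in cands)))
    vals = np.abs(np.cos(cands[:, None] - th[None, :])).sum(axis=1)
    best = vals.max()
    return float(cands[vals >= best - 1e-9][0])


def consensus_orientation(cell) -> float:
    """Consensus orientation (rad, [0, pi)) of a cell's podia."""
    if not cell.podia:
        raise ValueError("cell has no podia")
    return consensus_orientation_angles([p.angle for p in cell.podia])


def _positions_orientations(cells):
    pos, ori = [], []
    for c in cells:
        if c.podia:
            pos.append(np.asarray(c.center, float))
            ori.append(consensus_orientation(c))
    return np.asarray(pos), np.asarray(ori)


def order_parameter_profile(cells, bin_width: float = _DEFAULT_BIN,
                            max_distance: float = _DEFAULT_RANGE):
    """S(d) per centre-distance bin; empty bins are NaN (missing).

    Returns ``(bin_edges, S)`` with ``len(S) = len(bin_edges) - 1``.
    ``cells`` may be Cell objects (orientation from podia; podia-free
    cells are excluded) or ``(positions, orientations)`` arrays.
    """
    if isinstance(cells, tuple):
        pos, ori = (np.asarray(v, float) for v in cells)
    else:
        pos, ori = _positions_orientations(cells)
    if len(pos) < 2:
        raise ValueError("order parameter requires at least two oriented cells")
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    ii, jj = np.triu_indices(len(pos), k=1)
    d = np.hypot(*(pos[ii] - pos[jj]).T)
    keep = d <= max_distance
    ii, jj, d = ii[keep], jj[keep], d[keep]
    s_pair = np.cos(2.0 * (ori[ii] - ori[jj]))
    which = np.minimum(np.searchsorted(edges, d, side="right") - 1,
                       len(edges) - 2)
    s = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        m = which == b
        if m.any():
            s[b] = s_pair[m].mean()
    return edges, s


def order_parameter_star(cells, bin_width: float = _DEFAULT_BIN,
                         max_distance: float = _DEFAULT_RANGE) -> float:
    """S*: unweighted mean of S(d) over occupied bins within 50 um."""
    _, s = order_parameter_profile(cells, bin_width, max_distance)
    occ = ~np.isnan(s)
    if not occ.any():
        raise ValueError("no cell pairs within the averaging range")
    return float(s[occ].mean())


def mean_population_radius(cells, center=(0.0, 0.0)) -> float:
    """Mean radial cell position relative to the culture centre (um)."""
    pos = np.asarray([np.asarray(c.center, float) for c in cells]) \
        if not isinstance(cells, np.ndarray) else np.asarray(cells, float)
    if len(pos) == 0:
        raise ValueError("mean population radius of an empty population")
    c = np.asarray(center, float)
    return float(np.hypot(*(pos - c).T).mean())


def aspect_ratio(cells, center=(0.0, 0.0)) -> float:
    """<|y - y_c|> / <|x - x_c|> of the population."""
    pos = np.asarray([np.asarray(c.center, float) for c in cells]) \
        if not isinstance(cells, np.ndarray) else np.asarray(cells, float)
    if len(pos) == 0:
        raise ValueError("aspect ratio of an empty population")
    c = np.asarray(center, float)
    mx = np.abs(pos[:, 0] - c[0]).mean()
    my = np.abs(pos[:, 1] - c[1]).mean()
    if mx == 0:
        raise ValueError("aspect ratio undefined: zero x-extent")
    return float(my / mx)


def mean_podium_length(cells) -> float:
    """Mean podium length over all podia of the population (um)."""
    lengths = [p.length for c in cells for p in c.podia]
    if not lengths:
        raise ValueError("no podia in the population")
    return float(np.mean(lengths))


def msd_kinetic_exponent(trajectories, lags, dt: float = 1.0):
    """Local MSD exponent beta = d ln msd / d ln t at the given lags.

    ``trajectories`` has shape (T, n, 2) (time, track, xy) with uniform
    sampling interval ``dt`` (same time unit as ``lags``).  The MSD is
    averaged over tracks and all time origins; beta is obtained by central
    differences of log(msd) against log(lag) (one-sided at the ends).

    Returns ``(msd, beta)`` arrays aligned with ``lags``.
    """
    traj = np.asarray(trajectories, float)
    lags = np.asarray(lags, float)
    if lags.size < 2:
        raise ValueError("need at least two lags")
    steps = np.round(lags / dt).astype(int)
    if np.any(steps < 1) or np.any(steps >= traj.shape[0]):
        raise ValueError("lags outside the trajectory range")
    msd = np.empty(len(steps))
    for k, s in enumerate(steps):
        disp = traj[s:] - traj[:-s]
        msd[k] = (disp**2).sum(axis=-1).mean()
    if np.any(msd <= 0):
        raise ValueError("non-positive MSD; tracks do not move")
    lm, lt = np.log(msd), np.log(steps * dt)
    beta = np.gradient(lm, lt)
    return msd, beta


def filter_frame(cells, frame, center=(0.0, 0.0)):
    """Cells whose centres lie inside the evaluation rectangle."""
    if frame is None:
        return list(cells)
    w, h = frame
    cx, cy = center
    return [c for c in cells
            if abs(c.center[0] - cx) <= w / 2.0
            and abs(c.center[1] - cy) <= h / 2.0]


def population_metrics(cells, t: float, frame=None) -> dict:
    """One row of the standard time-series: counts, spread, order, length."""
    inframe = filter_frame(cells, frame)
    row = {"t": t, "n_cells": len(cells), "n_in_frame": len(inframe)}
    try:
        row["mean_radius"] = mean_population_radius(inframe)
    except ValueError:
        row["mean_radius"] = np.nan
    try:
        row["s_star"] = order_parameter_star(inframe)
    except ValueError:
        row["s_star"] = np.nan
    try:
        row["aspect_ratio"] = aspect_ratio(inframe)
    except ValueError:
        row["aspect_ratio"] = np.nan
    try:
        row["mean_podium_length"] = mean_podium_length(inframe)
    except ValueError:
        row["mean_podium_length"] = np.nan
    return row
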