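"""Image analysis: segmentation and per-cell orientation from micrographs.

Grayscale micrographs are segmented by two-cluster fuzzy c-means on pixel
intensity (membership exponent 2), hard-assigned to the brighter cluster,
connected-component labelled, and components below a minimum size are
discarded.  Each region contributes its centroid and the direction of the
main principal axis of its second central moments, yielding the same
(position, orientation) tables that the simulation metrics consume.

A synthetic renderer draws simulation states as bright bodies and podium
cones on a dark background with additive Gaussian noise, closing the loop
render -> segment -> orient against the model's consensus orientations
without requiring any experimental data.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from skimage import draw as _draw
from skimage import measure as _measure

__all__ = ["fuzzy_cmeans_intensity", "segment_cells", "region_orientation",
           "render_state", "orientation_table"]

MIN_REGION_PX = 50


def fuzzy_cmeans_intensity(values, c: int = 2, m: float = 2.0,
                           tol: float = 1e-5, max_iter: int = 300,
                           init=None):
    """1-D fuzzy c-means on intensity values.

    Returns ``(centers, memberships)`` with centers ascending and
    memberships of shape (len(values), c).  Deterministic: centres start
    at evenly spaced quantiles unless ``init`` is given.
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("no values to cluster")
    if init is None:
        qs = np.linspace(0.0, 1.0, c + 2)[1:-1]
        centers = np.quantile(v, qs)
        if np.allclose(centers, centers[0]):
            centers = centers + np.arange(c) * 1e-12
    else:
        centers = np.asarray(init, float)
    power = 2.0 / (m - 1.0)
    u = None
    for _ in range(max_iter):
        dist = np.abs(v[:, None] - centers[None, :])
        dist = np.maximum(dist, 1e-12)
        inv = dist ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        new_centers = (um * v[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            break
    order = np.argsort(centers)
    return centers[order], u[:, order]


def segment_cells(image, min_region_px: int = MIN_REGION_PX):
    """Label mask of cell regions in a single-channel image.

    Pixels are hard-assigned to the brighter fuzzy c-means cluster; a
    constant image yields an empty mask.
    """
    img = np.asarray(image, float)
    if img.ndim != 1 and img.ndim != 2:
        raise ValueError("segment_cells expects a single-channel image")
    flat = img.ravel()
    if np.ptp(flat) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    _, u = fuzzy_cmeans_intensity(flat)
    fg = (u[:, -1] > 0.5).reshape(img.shape)
    labels = _measure.label(fg, connectivity=2)
    if min_region_px > 1:
        counts = np.bincount(labels.ravel())
        drop = np.flatnonzero(counts < min_region_px)
        mask = np.isin(labels, drop[drop > 0])
        labels[mask] = 0
        labels, _, _ = _relabel(labels)
    return labels.astype(np.int32)


def _relabel(labels):
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out, ids, len(ids)


def region_orientation(mask, min_axis_ratio: float = 1.05):
    """Centroid, principal-axis angle and axis lengths per labelled region.

    The angle is reported in [0, pi) measured from the x-axis (image
    column direction).  Nearly isotropic regions (major/minor below
    ``min_axis_ratio``) and single-pixel regions are dropped -- their
    orientation is undefined.
    """
    rows = []
    for rp in _measure.regionprops(np.asarray(mask)):
        if rp.area < 2 or rp.axis_minor_length == 0:
            continue
        if rp.axis_major_length / rp.axis_minor_length < min_axis_ratio:
            continue
        cy, cx = rp.centroid  # (row, col)
        # skimage orientation: angle between the row axis and the major
        # axis; convert to the angle against the x (column) axis
        ang = (math.pi / 2.0 - rp.orientation) % math.pi
        rows.append({"label": rp.label, "x": cx, "y": cy,
                     "angle": ang, "major": rp.axis_major_length,
                     "minor": rp.axis_minor_length})
    return pd.DataFrame(rows, columns=["label", "x", "y", "angle",
                                       "major", "minor"])


def render_state(state, frame: Tuple[float, float], resolution: float = 1.0,
                 noise_sigma: float = 0.05, rng=None,
                 foreground: float = 1.0) -> np.ndarray:
    """Synthetic micrograph of a simulation state.

    ``frame`` is the imaged rectangle (width, height) in um centred on the
    origin; ``resolution`` is um per pixel.  Cell bodies are drawn as
    bright discs of the adhesion radius and podia as cones; additive
    Gaussian noise with the given sigma is applied.  Deterministic for a
    fixed rng seed.  Image rows follow +y so orientations carry over.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    w, h = frame
    nx = int(round(w / resolution))
    ny = int(round(h / resolution))
    img = np.zeros((ny, nx), float)

    def to_px(x, y):
        return ((x + w / 2.0) / resolution, (y + h / 2.0) / resolution)

    cells = state.cells() if hasattr(state, "cells") else list(state)
    params = getattr(state, "params", None)
    tipfrac = params.cone_tip_frac if params is not None else 0.6
    for c in cells:
        a = c.adhesion_radius
        cx, cy = to_px(*c.center)
        rr, cc = _draw.disk((cy, cx), max(a / resolution, 1.0),
                            shape=img.shape)
        img[rr, cc] = foreground
        rt = tipfrac * a
        for p in c.podia:
            tx = c.center[0] + (a / 2.0 + p.length) * math.cos(p.angle)
            ty = c.center[1] + (a / 2.0 + p.length) * math.sin(p.angle)
            txp, typ = to_px(tx, ty)
            ux, uy = -math.sin(p.angle), math.cos(p.angle)
            poly_r = [cy + uy * a / resolution, cy - uy * a / resolution,
                      typ - uy * rt / resolution, typ + uy * rt / resolution]
            poly_c = [cx + ux * a / resolution, cx - ux * a / resolution,
                      txp - ux * rt / resolution, txp + ux * rt / resolution]
            rr, cc = _draw.polygon(poly_r, poly_c, shape=img.shape)
            img[rr, cc] = foreground
            rr, cc = _draw.disk((typ, txp), max(rt / resolution, 1.0),
                                shape=img.shape)
            img[rr, cc] = foreground
    img += rng.normal(0.0, noise_sigma, img.shape)
    return img


def orientation_table(image, resolution: float = 1.0,
                      frame: Optional[Tuple[float, float]] = None,
                      min_region_px: int = MIN_REGION_PX) -> pd.DataFrame:
    """Segment an image and return (x, y, angle, major, minor) in um.

    With ``frame`` given, pixel coordinates are mapped back to the
    frame-centred um coordinate system used by the simulation.
    """
    mask = segment_cells(image, min_region_px=min_region_px)
    tab = region_orientation(mask)
    tab["x"] = tab["x"] * resolution
    tab["y"] = tab["y"] * resolution
    tab["major"] = tab["major"] * resolution
    tab["minor"] = tab["minor"] * resolution
    if frame is not None:
        tab["x"] -= frame[0] / 2.0
        tab["y"] -= frame[1] / 2.0
    return tab
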