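"""Micro-structured substrate patterns.

Grooves are modelled purely in 2D as never-moving stripe segments that
podia can align to: each groove has an anchor point, an axis direction, a
half-width and a half-length (infinite for parallel stripe patterns).
Three constructors cover the study's substrates: plain (no grooves),
parallel stripes, and the starlike plating unit optionally tiled on a
hexagonal lattice.  Membership queries use closed intervals so boundary
points count as inside, which keeps the classification deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

__all__ = [
    "Groove", "SubstratePattern", "plain", "parallel_grooves",
    "star_lattice", "point_in_groove", "pattern_from_file",
]

_INF = 1e9


@dataclass(frozen=True)
class Groove:
    """One rectangular groove stripe (possibly infinite along its axis)."""

    anchor_x: float
    anchor_y: float
    angle: float       # axis direction, rad
    half_width: float
    half_length: float = _INF

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("groove half-width must be > 0")

    def local_coords(self, px, py):
        """(along-axis, across-axis) coordinates of points."""
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        dx = np.asarray(px, float) - self.anchor_x
        dy = np.asarray(py, float) - self.anchor_y
        return dx * ca + dy * sa, -dx * sa + dy * ca

    def contains(self, px, py):
        lon, lat = self.local_coords(px, py)
        return (np.abs(lat) <= self.half_width) & (np.abs(lon) <= self.half_length)

    def axis_distance(self, px, py):
        _, lat = self.local_coords(px, py)
        return np.abs(lat)


class SubstratePattern:
    """A named collection of grooves."""

    def __init__(self, kind: str, grooves: List[Groove]):
        self.kind = kind
        self.grooves = list(grooves)

    def __len__(self) -> int:
        return len(self.grooves)

    @property
    def has_grooves(self) -> bool:
        return len(self.grooves) > 0


def plain() -> SubstratePattern:
    """Homogeneous substrate without micro-structure."""
    return SubstratePattern("plain", [])


def parallel_grooves(width: float = 8.0, spacing: float = 8.0,
                     extent: float = 1000.0) -> SubstratePattern:
    """Parallel stripes along the y-axis at pitch ``width + spacing``.

    Stripe centres sit at x = k * pitch for integer k; ``extent`` bounds the
    covered x-range (grooves themselves are infinite along y).
    """
    if width <= 0 or spacing <= 0:
        raise ValueError("groove width and spacing must be > 0")
    pitch = width + spacing
    kmax = int(math.ceil(extent / pitch))
    grooves = [Groove(k * pitch, 0.0, math.pi / 2.0, width / 2.0)
               for k in range(-kmax, kmax + 1)]
    return SubstratePattern("parallel", grooves)


def star_lattice(arms: int = 8, groove_width: float = 8.0,
                 groove_spacing: float = 8.0, unit_radius: float = 400.0,
                 lattice_pitch: Optional[float] = None,
                 grooves_per_arm: int = 3, n_rings: int = 0) -> SubstratePattern:
    """Starlike plating unit(s): radial groove bundles on a hexagonal lattice.

    Each unit carries ``arms`` bundles at equal angular spacing; a bundle is
    ``grooves_per_arm`` parallel finite grooves along the radial direction,
    laterally offset at pitch ``groove_width + groove_spacing``, reaching
    from the unit centre out to ``unit_radius``.  ``n_rings = 0`` gives the
    single-unit mode; otherwise units are tiled on a hexagonal lattice of
    the given pitch (default ``2 * unit_radius``).
    """
    if arms < 3:
        raise ValueError("a starlike unit needs at least 3 arms")
    if lattice_pitch is None:
        lattice_pitch = 2.0 * unit_radius
    pitch = groove_width + groove_spacing
    centers = [(0.0, 0.0)]
    for ring in range(1, n_rings + 1):
        for k in range(6 * ring):
            # walk the hexagonal ring
            corner = k // ring
            step = k % ring
            a0 = math.pi / 3.0 * corner
            a1 = math.pi / 3.0 * (corner + 2)
            cxy = (ring * lattice_pitch * math.cos(a0)
                   + step * lattice_pitch * math.cos(a1),
                   ring * lattice_pitch * math.sin(a0)
                   + step * lattice_pitch * math.sin(a1))
            centers.append(cxy)
    grooves = []
    half_len = unit_radius / 2.0
    side = (grooves_per_arm - 1) / 2.0
    for ucx, ucy in centers:
        for m in range(arms):
            ang = 2.0 * math.pi * m / arms
            ca, sa = math.cos(ang), math.sin(ang)
            for g in range(grooves_per_arm):
                off = (g - side) * pitch
                ax = ucx + half_len * ca - off * sa
                ay = ucy + half_len * sa + off * ca
                grooves.append(Groove(ax, ay, ang, groove_width / 2.0, half_len))
    return SubstratePattern("star_lattice", grooves)


def point_in_groove(pattern: SubstratePattern, point):
    """Groove containing a point, or None; nearest axis wins on overlap."""
    px, py = float(point[0]), float(point[1])
    best = None
    best_d = np.inf
    for g in pattern.grooves:
        if g.contains(px, py):
            d = float(g.axis_distance(px, py))
            if d < best_d:
                best, best_d = g, d
    return best


def pattern_from_file(path) -> SubstratePattern:
    """Read grooves from text: one per line,
    ``anchor_x anchor_y angle_rad half_width [half_length]``."""
    grooves = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (4, 5):
                raise ValueError(f"{path}:{ln}: expected 4 or 5 fields")
            vals = [float(v) for v in parts]
            hl = vals[4] if len(vals) == 5 else _INF
            grooves.append(Groove(vals[0], vals[1], vals[2], vals[3], hl))
    return SubstratePattern("file", grooves)
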