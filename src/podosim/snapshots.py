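"""Snapshot files: auditable CSV state dumps plus a JSON manifest.

A snapshot file holds two CSV tables separated by a blank line: a cell
table (one row per cell) and a podium table (one row per podium).  The
manifest (``<snapshot>.manifest.json``) embeds the full parameter set in
table units, the seed and the package version, so any figure-style output
can be recomputed from disk alone.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .metrics import consensus_orientation_angles
from .params import ModelParameters
from .state import Cell, Podium

__all__ = ["write_snapshot", "read_snapshot", "SnapshotError"]

CELL_COLUMNS = ["cell_id", "x_um", "y_um", "radius_um", "height_um",
                "v_target_um3", "v_actual_um3", "phase", "n_podia_active",
                "n_podia_total", "consensus_angle_rad"]
PODIUM_COLUMNS = ["cell_id", "podium_index", "angle_rad", "length_um",
                  "active", "precedence"]


class SnapshotError(ValueError):
    pass


def write_snapshot(state, path, seed: Optional[int] = None) -> Path:
    """Write the state to ``path`` and its manifest alongside."""
    path = Path(path)
    cells = state.cells() if hasattr(state, "cells") else list(state)
    crow, prow = [], []
    for c in cells:
        angs = [p.angle for p in c.podia]
        cons = consensus_orientation_angles(angs) if angs else ""
        crow.append([c.id, repr(float(c.center[0])), repr(float(c.center[1])),
                     repr(float(c.R)), repr(float(c.height)),
                     repr(float(c.V_target)), repr(float(c.V_actual)),
                     c.phase, sum(p.active for p in c.podia), len(c.podia),
                     repr(float(cons)) if cons != "" else ""])
        for k, p in enumerate(c.podia):
            prow.append([c.id, k, repr(float(p.angle)), repr(float(p.length)),
                         int(p.active), p.precedence])
    with open(path, "w") as fh:
        fh.write(",".join(CELL_COLUMNS) + "\n")
        for row in crow:
            fh.write(",".join(str(v) for v in row) + "\n")
        fh.write("\n")
        fh.write(",".join(PODIUM_COLUMNS) + "\n")
        for row in prow:
            fh.write(",".join(str(v) for v in row) + "\n")
    manifest = {
        "format": "podosim-snapshot-1",
        "version": __version__,
        "t_days": float(getattr(state, "t", 0.0)),
        "seed": seed,
        "n_cells": len(cells),
        "written": datetime.now(timezone.utc).isoformat(),
        "parameters": _jsonable(state.params.to_table_units())
        if hasattr(state, "params") else None,
    }
    with open(str(path) + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


def read_snapshot(path) -> List[Cell]:
    """Reconstruct cells (with podia) from a snapshot file.

    Sufficient for all analysis statistics; the random stream is not part
    of a snapshot, so bit-exact resumption is out of scope.  Unknown extra
    columns are accepted; malformed rows raise with their line number.
    """
    path = Path(path)
    text = path.read_text()
    parts = text.split("\n\n", 1)
    if len(parts) != 2:
        raise SnapshotError(f"{path}: missing podium table separator")
    import io as _io

    try:
        cdf = pd.read_csv(_io.StringIO(parts[0]))
        pdf = pd.read_csv(_io.StringIO(parts[1]))
    except Exception as exc:
        raise SnapshotError(f"{path}: unparsable CSV: {exc}") from exc
    for col in CELL_COLUMNS:
        if col not in cdf.columns and col != "consensus_angle_rad":
            raise SnapshotError(f"{path}: missing cell column {col!r}")
    for col in PODIUM_COLUMNS:
        if col not in pdf.columns:
            raise SnapshotError(f"{path}: missing podium column {col!r}")
    n_header = 1
    cells = {}
    for ln, row in enumerate(cdf.itertuples(index=False), start=n_header + 1):
        try:
            cid = int(row.cell_id)
            cells[cid] = Cell(
                center=np.array([float(row.x_um), float(row.y_um)]),
                R=float(row.radius_um), V_target=float(row.v_target_um3),
                height=float(row.height_um), phase=int(row.phase),
                V_actual=float(row.v_actual_um3), id=cid)
        except (TypeError, ValueError) as exc:
            raise SnapshotError(f"{path}:{ln}: bad cell row: {exc}") from exc
    pstart = n_header + len(cdf) + 2
    for ln, row in enumerate(pdf.itertuples(index=False), start=pstart + 1):
        try:
            cid = int(row.cell_id)
            pod = Podium(angle=float(row.angle_rad),
                         length=float(row.length_um),
                         active=bool(int(row.active)),
                         precedence=int(row.precedence))
        except (TypeError, ValueError) as exc:
            raise SnapshotError(f"{path}:{ln}: bad podium row: {exc}") from exc
        if cid not in cells:
            raise SnapshotError(f"{path}:{ln}: podium for unknown cell {cid}")
        cells[cid].podia.append(pod)
    return [cells[k] for k in sorted(cells)]
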