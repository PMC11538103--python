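"""Serialization of branch tracks, configs and polyline geometry.

Branch tracks round-trip through JSON; centerline polylines are also
exported as legacy ASCII VTK PolyData so they open in standard viewers.
"""

from __future__ import annotations

import json

import numpy as np

from .tracking import BranchTrack

__all__ = ["save_branches", "load_branches", "write_vtk_polylines"]


def save_branches(tracks: list[BranchTrack], path) -> None:
    payload = []
    for t in tracks:
        payload.append({
            "points": np.asarray(t.points).tolist(),
            "radii": np.asarray(t.radii).tolist(),
            "parent": list(t.parent) if t.parent is not None else None,
            "order": int(t.order),
            "provenance": t.provenance,
        })
    with open(path, "w") as fh:
        json.dump({"branches": payload}, fh, indent=1)


def load_branches(path) -> list[BranchTrack]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for b in payload["branches"]:
        out.append(BranchTrack(
            points=np.asarray(b["points"], dtype=float),
            radii=np.asarray(b["radii"], dtype=float),
            parent=tuple(b["parent"]) if b["parent"] is not None else None,
            order=int(b["order"]), provenance=b.get("provenance", "seed")))
    return out


def write_vtk_polylines(tracks: list[BranchTrack], path) -> None:
    """Legacy ASCII VTK PolyData: one polyline per branch, radius as point data."""
    points = []
    lines = []
    radii = []
    offset = 0
    for t in tracks:
        n = len(t.points)
        points.extend(np.asarray(t.points).tolist())
        radii.extend(np.asarray(t.radii).tolist())
        lines.append([n] + list(range(offset, offset + n)))
        offset += n
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvessel centerlines\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(i) for i in l) + "\n")
        fh.write(f"POINT_DATA {len(points)}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for r in radii:
            fh.write(f"{r:.6f}\n")
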