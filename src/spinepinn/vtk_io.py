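"""VTK legacy (ASCII) unstructured-grid interchange for labeled tet meshes.

Writes nodes, tetrahedra, the region label of every cell as CELL_DATA, and
optionally per-point/per-cell field arrays (e.g. displacement, stress).
The endplate node sets and region names are stored in the header comment
line as JSON so a mesh round-trips losslessly through a single file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .geometry import LabeledTetMesh, _boundary_faces

__all__ = ["write_vtk", "read_vtk"]

_VTK_TET = 10


def write_vtk(
    mesh: LabeledTetMesh,
    path,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write a labeled tet mesh (plus optional fields) as legacy ASCII VTK."""
    path = Path(path)
    meta = {
        "region_names": mesh.region_names,
        "endplate_sets": {k: v.tolist() for k, v in mesh.endplate_sets.items()},
    }
    lines = [
        "# vtk DataFile Version 3.0",
        "spinepinn " + json.dumps(meta),
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.nodes)} double",
    ]
    lines += [" ".join(repr(float(x)) for x in row) for row in mesh.nodes]
    m = len(mesh.tets)
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(str(int(i)) for i in row) for row in mesh.tets]
    lines.append(f"CELL_TYPES {m}")
    lines += [str(_VTK_TET)] * m

    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region_label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(l)) for l in mesh.region_labels]
    for name, arr in (cell_data or {}).items():
        lines += _field_lines(name, np.asarray(arr), m)
    if point_data:
        lines.append(f"POINT_DATA {len(mesh.nodes)}")
        for name, arr in point_data.items():
            lines += _field_lines(name, np.asarray(arr), len(mesh.nodes))
    path.write_text("\n".join(lines) + "\n")


def _field_lines(name, arr, n):
    if arr.shape[0] != n:
        raise ValueError(f"field {name!r} has {arr.shape[0]} entries, expected {n}")
    if arr.ndim == 1:
        arr = arr[:, None]
    ncomp = arr.shape[1]
    if ncomp == 3:
        out = [f"VECTORS {name} double"]
    else:
        out = [f"SCALARS {name} double {ncomp}", "LOOKUP_TABLE default"]
    out += [" ".join(repr(float(x)) for x in row) for row in arr]
    return out


def read_vtk(path) -> LabeledTetMesh:
    """Read a legacy ASCII VTK unstructured grid written by :func:`write_vtk`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise ValueError(f"{path}: not a legacy VTK file (bad header line 1)")
    meta = {}
    if lines[1].startswith("spinepinn "):
        meta = json.loads(lines[1][len("spinepinn "):])

    idx = {"POINTS": None, "CELLS": None, "CELL_TYPES": None}
    for i, line in enumerate(lines):
        key = line.split(" ", 1)[0]
        if key in idx and idx[key] is None:
            idx[key] = i
    if any(v is None for v in idx.values()):
        raise ValueError(f"{path}: missing POINTS/CELLS/CELL_TYPES sections")

    n_pts = int(lines[idx["POINTS"]].split()[1])
    pts = np.loadtxt(lines[idx["POINTS"] + 1 : idx["POINTS"] + 1 + n_pts]).reshape(n_pts, 3)

    n_cells = int(lines[idx["CELLS"]].split()[1])
    cell_rows = np.loadtxt(
        lines[idx["CELLS"] + 1 : idx["CELLS"] + 1 + n_cells], dtype=np.int64
    ).reshape(n_cells, 5)
    if np.any(cell_rows[:, 0] != 4):
        raise ValueError(f"{path}: only tetrahedral cells are supported")
    tets = cell_rows[:, 1:]

    labels = np.zeros(n_cells, dtype=np.int64)
    for i, line in enumerate(lines):
        if line.startswith("SCALARS region_label"):
            labels = np.loadtxt(lines[i + 2 : i + 2 + n_cells], dtype=np.int64).reshape(
                n_cells
            )
            break

    region_names = meta.get(
        "region_names", [f"region_{i}" for i in range(int(labels.max()) + 1)]
    )
    tris, tri_regions = _boundary_faces(pts, tets, labels)
    endplates = {
        k: np.asarray(v, dtype=np.int64)
        for k, v in meta.get("endplate_sets", {}).items()
    }
    return LabeledTetMesh(
        nodes=pts,
        tets=tets,
        region_labels=labels,
        region_names=list(region_names),
        boundary_triangles=tris,
        boundary_regions=tri_regions,
        endplate_sets=endplates,
    )
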