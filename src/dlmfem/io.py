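"""File I/O: STL (via trimesh), Gmsh MSH v4.1 (ASCII), legacy VTK, JSON configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def write_stl(path, vertices: np.ndarray, triangles: np.ndarray) -> None:
    mesh = trimesh.Trimesh(vertices=vertices, faces=triangles, process=False)
    mesh.export(str(path), file_type="stl")


def read_stl(path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load(str(path), file_type="stl", process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# Gmsh MSH v4.1 (ASCII) — minimal writer/reader for tri + tet meshes
# ---------------------------------------------------------------------------

_MSH_TYPES = {"triangle": 2, "tet": 4}
_MSH_DIM = {"triangle": 2, "tet": 3}
_MSH_NODES_PER = {2: 3, 4: 4}


def write_msh(path, nodes: np.ndarray,
              elements: dict[str, np.ndarray]) -> None:
    """Write nodes + element blocks; keys of ``elements`` are 'triangle'/'tet'."""
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    n = len(nodes)
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 1 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [f"{x:.16g} {y:.16g} {z:.16g}" for x, y, z in nodes]
    lines += ["$EndNodes"]
    total = sum(len(v) for v in elements.values())
    lines += ["$Elements", f"{len(elements)} {total} 1 {total}"]
    eid = 1
    for tag, (name, conn) in enumerate(elements.items(), start=1):
        etype = _MSH_TYPES[name]
        lines.append(f"{_MSH_DIM[name]} {tag} {etype} {len(conn)}")
        for row in conn:
            lines.append(" ".join([str(eid)] + [str(int(v) + 1) for v in row]))
            eid += 1
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines))


def read_msh(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def seek(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"section {tag} not found")

    seek("$Nodes")
    header = next(it).split()
    nblocks, n = int(header[0]), int(header[1])
    nodes = np.empty((n, 3))
    pos = 0
    for _ in range(nblocks):
        bn = int(next(it).split()[3])
        ids = [int(next(it)) for _ in range(bn)]
        for k in range(bn):
            nodes[ids[k] - 1] = [float(v) for v in next(it).split()[:3]]
        pos += bn
    seek("$Elements")
    header = next(it).split()
    nblocks = int(header[0])
    elements: dict[str, list] = {}
    inv_types = {v: k for k, v in _MSH_TYPES.items()}
    for _ in range(nblocks):
        _, _, etype, count = (int(v) for v in next(it).split())
        name = inv_types[etype]
        conn = elements.setdefault(name, [])
        for _ in range(count):
            row = next(it).split()
            conn.append([int(v) - 1 for v in row[1:1 + _MSH_NODES_PER[etype]]])
    return nodes, {k: np.asarray(v, dtype=np.int64) for k, v in elements.items()}


# ---------------------------------------------------------------------------
# Legacy VTK (unstructured grid, ASCII) — element fields
# ---------------------------------------------------------------------------

def write_vtk(path, nodes: np.ndarray, tets: np.ndarray,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    lines = ["# vtk DataFile Version 3.0", "dlmfem field export", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(nodes)} double"]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in nodes]
    lines.append(f"CELLS {len(tets)} {5 * len(tets)}")
    lines += ["4 " + " ".join(str(int(v)) for v in row) for row in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)
    if cell_data:
        lines.append(f"CELL_DATA {len(tets)}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.dtype.kind in "if":
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]
            else:  # string labels -> integer codes
                labels, codes = np.unique(arr, return_inverse=True)
                lines.append(f"SCALARS {name} int 1")
                lines.append("LOOKUP_TABLE default")
                lines += [str(int(v)) for v in codes]
    lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# JSON config round-trip
# ---------------------------------------------------------------------------

def dump_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
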