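"""Structured tetrahedral meshing primitives.

All solids in this package are generated parametrically: a 2-D triangulation
(polar/elliptic grids for joint tissues, rectilinear grids for benchmark
blocks) is extruded between two z-surfaces and every prism is split into
three tetrahedra.  Quad/prism diagonals follow a deterministic lowest-rank
vertex rule (ranks from sorted coordinates), which guarantees a conforming
(crack-free) tetrahedralization across element boundaries and makes
reflected geometries mesh into exactly reflected elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# 2-D grids
# ---------------------------------------------------------------------------

@dataclass
class Grid2D:
    """A 2-D triangulation plus the structured indexing it came from."""

    points: np.ndarray          # (N, 2)
    triangles: np.ndarray       # (M, 3)
    node_id: np.ndarray         # (ntheta, nr) or (nx, ny) structured index map
    rho: np.ndarray | None = None      # per-node radial coordinate (polar grids)
    theta: np.ndarray | None = None    # per-node angle (polar grids)


def _column_ranks(points: np.ndarray) -> np.ndarray:
    """Deterministic vertex ordering used for diagonal selection.

    Ranks are lexicographic on the rounded coordinates (x, |y|), with the
    node index as a final tie-break.  Using |y| makes the rule equivariant
    under reflection in the anterior-posterior axis, so mirrored geometries
    triangulate into exactly mirrored elements (vertices at +y and -y of the
    same x, which do tie, are never compared against each other in a
    structured grid)."""
    x = np.round(points[:, 0], 9)
    ay = np.round(np.abs(points[:, 1]), 9)
    order = np.lexsort((np.arange(len(points)), ay, x))
    rank = np.empty(len(points), dtype=np.int64)
    rank[order] = np.arange(len(points))
    return rank


def _split_quad(a: int, b: int, c: int, d: int,
                rank: np.ndarray) -> list[tuple[int, int, int]]:
    """Split CCW quad (a,b,c,d) along the diagonal through its lowest-rank
    vertex."""
    if min(rank[a], rank[c]) < min(rank[b], rank[d]):
        return [(a, b, c), (a, c, d)]
    return [(b, c, d), (b, d, a)]


def polar_grid(center: tuple[float, float], a: float, b: float,
               theta: np.ndarray, rho_cols: np.ndarray) -> Grid2D:
    """Triangulate an elliptic annulus/disc.

    Parameters
    ----------
    center, a, b:
        Ellipse center and semi-axes (ML, AP).
    theta:
        Angles of the ``ntheta`` columns (full circle, no duplicate seam).
    rho_cols:
        (ntheta, nr) monotone radial coordinates per column, in [0, 1].
        If the innermost level is identically zero the center collapses to a
        single node (solid disc with a triangle fan).
    """
    ntheta, nr = rho_cols.shape
    if np.any(np.diff(rho_cols, axis=1) <= 0):
        raise ValueError("rho_cols must be strictly increasing along each column")
    collapsed = bool(np.all(rho_cols[:, 0] == 0.0))

    xc, yc = center
    ids = np.empty((ntheta, nr), dtype=np.int64)
    pts: list[np.ndarray] = []
    rho_out: list[float] = []
    th_out: list[float] = []
    if collapsed:
        pts.append(np.array([xc, yc]))
        rho_out.append(0.0)
        th_out.append(0.0)
        ids[:, 0] = 0
        i0 = 1
    else:
        i0 = 0
    nid = len(pts)
    for j in range(ntheta):
        for i in range(i0, nr):
            r = rho_cols[j, i]
            pts.append(np.array([xc + a * r * np.cos(theta[j]),
                                 yc + b * r * np.sin(theta[j])]))
            rho_out.append(r)
            th_out.append(theta[j])
            ids[j, i] = nid
            nid += 1
    points = np.asarray(pts)

    rank = _column_ranks(points)
    tris: list[tuple[int, int, int]] = []
    for j in range(ntheta):
        jn = (j + 1) % ntheta
        start = 0
        if collapsed:
            tris.append((0, ids[j, 1], ids[jn, 1]))
            start = 1
        for i in range(start, nr - 1):
            # CCW quad with theta increasing j -> jn, rho increasing i -> i+1
            tris.extend(_split_quad(ids[j, i], ids[jn, i],
                                    ids[jn, i + 1], ids[j, i + 1], rank))
    return Grid2D(points=points, triangles=np.asarray(tris, dtype=np.int64),
                  node_id=ids, rho=np.asarray(rho_out), theta=np.asarray(th_out))


def rect_grid(x: np.ndarray, y: np.ndarray) -> Grid2D:
    """Triangulated rectilinear grid (benchmark blocks)."""
    nx, ny = len(x), len(y)
    ids = np.arange(nx * ny).reshape(nx, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    points = np.column_stack([xx.ravel(), yy.ravel()])
    rank = _column_ranks(points)
    tris: list[tuple[int, int, int]] = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            tris.extend(_split_quad(ids[i, j], ids[i + 1, j],
                                    ids[i + 1, j + 1], ids[i, j + 1], rank))
    return Grid2D(points=points, triangles=np.asarray(tris, dtype=np.int64),
                  node_id=ids)


# ---------------------------------------------------------------------------
# Prism extrusion
# ---------------------------------------------------------------------------

@dataclass
class TetBlock:
    """One extruded solid: tets plus the structured node sets downstream
    stages (contact pairing, boundary conditions) need."""

    nodes: np.ndarray           # (N, 3)
    tets: np.ndarray            # (M, 4), positive signed volume
    bottom_nodes: np.ndarray    # node ids of the k=0 layer
    top_nodes: np.ndarray       # node ids of the k=nz layer
    bottom_tris: np.ndarray     # (t, 3) surface triangles on the bottom layer
    top_tris: np.ndarray
    grid: Grid2D = None
    outer_rim_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def _prism_tets(p0: int, p1: int, p2: int, q0: int, q1: int, q2: int,
                r0: int, r1: int, r2: int) -> list[tuple]:
    """Split prism (bottom p0p1p2 / top q0q1q2) into 3 tets.

    Diagonals of the three vertical quads run from the bottom vertex of the
    lower-ranked column to the top vertex of the other, which is conforming
    across neighbouring prisms and mirror-equivariant (ranks come from
    ``_column_ranks`` of the base triangulation)."""
    order = np.argsort([r0, r1, r2])
    b = [p0, p1, p2]
    t = [q0, q1, q2]
    rk = [r0, r1, r2]
    r = order[0]
    b = b[r:] + b[:r]
    t = t[r:] + t[:r]
    rk = rk[r:] + rk[:r]
    p0, p1, p2 = b
    q0, q1, q2 = t
    if rk[1] < rk[2]:               # quad12 diagonal through p1
        return [(p0, q0, q1, q2), (p0, p1, p2, q2), (p0, p1, q2, q1)]
    return [(p0, q0, q2, q1), (p0, p2, p1, q1), (p0, p2, q1, q2)]


def extrude(grid: Grid2D, z_bottom: np.ndarray, z_top: np.ndarray,
            nz: int, layer_fractions: np.ndarray | None = None) -> TetBlock:
    """Extrude a 2-D triangulation between two per-node z-surfaces.

    ``z_bottom``/``z_top`` are per-2D-node arrays; layer ``k`` sits at
    fraction ``layer_fractions[k]`` (uniform by default) between them.
    """
    n2 = len(grid.points)
    if layer_fractions is None:
        layer_fractions = np.linspace(0.0, 1.0, nz + 1)
    else:
        layer_fractions = np.asarray(layer_fractions, dtype=float)
        nz = len(layer_fractions) - 1
    if np.any(z_top - z_bottom <= 0):
        raise ValueError("extrusion requires z_top > z_bottom everywhere")

    nodes = np.empty(((nz + 1) * n2, 3))
    for k, f in enumerate(layer_fractions):
        z = z_bottom + f * (z_top - z_bottom)
        nodes[k * n2:(k + 1) * n2, 0:2] = grid.points
        nodes[k * n2:(k + 1) * n2, 2] = z

    rank = _column_ranks(grid.points)
    tets: list[tuple] = []
    for k in range(nz):
        off_b, off_t = k * n2, (k + 1) * n2
        for (i, j, m) in grid.triangles:
            tets.extend(_prism_tets(off_b + i, off_b + j, off_b + m,
                                    off_t + i, off_t + j, off_t + m,
                                    rank[i], rank[j], rank[m]))
    tets = np.asarray(tets, dtype=np.int64)
    tets = orient_tets(nodes, tets)

    bottom_nodes = np.arange(n2, dtype=np.int64)
    top_nodes = np.arange(nz * n2, (nz + 1) * n2, dtype=np.int64)
    bottom_tris = grid.triangles[:, ::-1].copy()          # outward = -z
    top_tris = grid.triangles + nz * n2                   # outward = +z
    outer = np.empty(0, dtype=np.int64)
    if grid.rho is not None:
        rmax = grid.rho.max()
        rim2d = np.where(grid.rho >= rmax - 1e-12)[0]
        outer = rim2d.astype(np.int64)                    # bottom-layer ids
    return TetBlock(nodes=nodes, tets=tets, bottom_nodes=bottom_nodes,
                    top_nodes=top_nodes, bottom_tris=bottom_tris,
                    top_tris=top_tris, grid=grid, outer_rim_nodes=outer)


# ---------------------------------------------------------------------------
# Mesh utilities
# ---------------------------------------------------------------------------

def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def orient_tets(nodes: np.ndarray, tets: np.ndarray,
                drop_degenerate: bool = True, tol: float = 1e-12) -> np.ndarray:
    """Flip inverted tets; optionally drop (near-)zero-volume ones."""
    v = tet_volumes(nodes, tets)
    tets = tets.copy()
    neg = v < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    if drop_degenerate:
        scale = np.abs(v).max() if len(v) else 1.0
        tets = tets[np.abs(v) > tol * max(scale, 1.0)]
    return tets


def boundary_surface(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a positively oriented tet mesh."""
    f = np.concatenate([
        tets[:, [0, 2, 1]],
        tets[:, [0, 1, 3]],
        tets[:, [1, 2, 3]],
        tets[:, [0, 3, 2]],
    ])
    key = np.sort(f, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return f[counts[inv] == 1]


def merge_duplicate_nodes(nodes: np.ndarray, tets: np.ndarray,
                          tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Weld coincident nodes (used after center-collapse constructions)."""
    key = np.round(nodes / tol).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True,
                              return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_nodes = nodes[np.sort(first)]
    remap = rank[inv]
    return new_nodes, remap[tets]


def surface_volume(vertices: np.ndarray, triangles: np.ndarray) -> float:
    """Signed enclosed volume of a closed triangulated surface
    (divergence theorem)."""
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 1]] - vertices[triangles[:, 0]]
    b = vertices[triangles[:, 2]] - vertices[triangles[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def node_tributary_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Per-vertex area share (1/3 of each incident triangle)."""
    areas = triangle_areas(vertices, triangles)
    out = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(out, triangles[:, k], areas / 3.0)
    return out


def clipped_tet_volume_below(nodes: np.ndarray, tets: np.ndarray,
                             axis: int, cut: float) -> float:
    """Total tet-mesh volume on the side ``coord <= cut`` (exact clipping).

    Used by the equal-volume anterior/posterior split search; handles tets
    straddling the plane by recursive corner decomposition.
    """
    vol = tet_volumes(nodes, tets)
    d = nodes[:, axis][tets] - cut          # (M, 4) signed distances
    below = d <= 0
    nb = below.sum(axis=1)
    total = vol[nb == 4].sum()
    for count in (1, 2, 3):
        idx = np.where(nb == count)[0]
        for e in idx:
            total += _tet_clip_volume(nodes[tets[e]], d[e])
    return float(total)


def _tet_clip_volume(x: np.ndarray, d: np.ndarray) -> float:
    """Volume of the part of one tet with signed distance d <= 0."""
    # nodes exactly on the plane are nudged to the positive side so the
    # corner-count case analysis terminates (volume effect is nil)
    d = np.where(np.abs(d) < 1e-9, 1e-9, d)
    below = d <= 0
    nb = int(below.sum())
    vol = abs(np.linalg.det(x[1:] - x[0])) / 6.0
    if nb == 0:
        return 0.0
    if nb == 4:
        return vol

    def cut_point(i, j):
        t = d[i] / (d[i] - d[j])
        return x[i] + t * (x[j] - x[i])

    if nb == 1:
        i = int(np.where(below)[0][0])
        others = [j for j in range(4) if j != i]
        corners = [x[i]] + [cut_point(i, j) for j in others]
        return abs(np.linalg.det(np.asarray(corners[1:]) - corners[0])) / 6.0
    if nb == 3:
        return vol - _tet_clip_volume(x, -d)
    # nb == 2: prism-shaped piece; decompose into 3 tets
    bi = list(np.where(below)[0])
    ai = list(np.where(~below)[0])
    p0, p1 = x[bi[0]], x[bi[1]]
    c00 = cut_point(bi[0], ai[0])
    c01 = cut_point(bi[0], ai[1])
    c10 = cut_point(bi[1], ai[0])
    c11 = cut_point(bi[1], ai[1])
    t1 = (p0, p1, c00, c01)
    t2 = (p1, c00, c01, c11)
    t3 = (p1, c00, c10, c11)
    s = 0.0
    for t in (t1, t2, t3):
        t = np.asarray(t)
        s += abs(np.linalg.det(t[1:] - t[0])) / 6.0
    return s


def dihedral_angles(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Dihedral angle (rad) across every interior edge of a surface mesh.

    Returns the deviation from a flat surface (0 = coplanar neighbours);
    used to quantify the sharpness of resection steps before/after blending.
    """
    from collections import defaultdict
    normals = np.cross(vertices[triangles[:, 1]] - vertices[triangles[:, 0]],
                       vertices[triangles[:, 2]] - vertices[triangles[:, 0]])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms == 0, 1.0, norms)
    edge_map = defaultdict(list)
    for t, tri in enumerate(triangles):
        for k in range(3):
            e = tuple(sorted((int(tri[k]), int(tri[(k + 1) % 3]))))
            edge_map[e].append(t)
    out = []
    for tris_ in edge_map.values():
        if len(tris_) == 2:
            c = float(np.clip(np.dot(normals[tris_[0]], normals[tris_[1]]),
                              -1.0, 1.0))
            out.append(np.arccos(c))
    return np.asarray(out)
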