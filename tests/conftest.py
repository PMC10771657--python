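import numpy as np
import pytest

from dlmfem import (GeometryConfig, PartitionScheme, build_discoid_meniscus,
                    partition_rings, split_anterior_posterior)
from dlmfem.geometry import MeshSizes


@pytest.fixture(scope="session")
def default_config():
    return GeometryConfig()


@pytest.fixture(scope="session")
def coarse_sizes():
    return MeshSizes(in_plane=2.0, nz_cartilage=2, nz_meniscus=2)


@pytest.fixture(scope="session")
def discoid(default_config, coarse_sizes):
    return build_discoid_meniscus(default_config, sizes=coarse_sizes)


@pytest.fixture(scope="session")
def partition(discoid, coarse_sizes):
    part = partition_rings(discoid, PartitionScheme(), sizes=coarse_sizes)
    return split_anterior_posterior(part)


@pytest.fixture
def rng():
    return np.random.default_rng(20240106)


# ---------------------------------------------------------------------------
# Brute-force geometric oracles (no spatial index needed)
# ---------------------------------------------------------------------------

def ray_z_crossings(vertices, triangles, x, y):
    """z-values where the vertical line through (x, y) crosses the surface."""
    a, b, c = (vertices[triangles[:, k]] for k in range(3))
    d = ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
         - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    ok = np.abs(d) > 1e-14
    a, b, c, d = a[ok], b[ok], c[ok], d[ok]
    w1 = ((b[:, 0] - x) * (c[:, 1] - y) - (c[:, 0] - x) * (b[:, 1] - y)) / d
    w2 = ((c[:, 0] - x) * (a[:, 1] - y) - (a[:, 0] - x) * (c[:, 1] - y)) / d
    w3 = 1.0 - w1 - w2
    hit = (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
    z = w1[hit] * a[hit, 2] + w2[hit] * b[hit, 2] + w3[hit] * c[hit, 2]
    return np.sort(z)


def points_inside_surface(vertices, triangles, points):
    """Vectorized parity test along +z columns (brute force, no index)."""
    inside = np.zeros(len(points), dtype=bool)
    # group points by column for efficiency
    cols = {}
    for i, p in enumerate(points):
        cols.setdefault((round(p[0], 9), round(p[1], 9)), []).append(i)
    for (x, y), idx in cols.items():
        z = ray_z_crossings(vertices, triangles, x, y)
        if len(z) == 0:
            continue
        for i in idx:
            inside[i] = np.searchsorted(z, points[i][2]) % 2 == 1
    return inside


def point_triangle_distance(p, a, b, c):
    """Exact distance from one point to one triangle."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(ap)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(bp)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return np.linalg.norm(ap - t * ab)
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(cp)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return np.linalg.norm(ap - t * ac)
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + t * (c - b)))
    n = np.cross(ab, ac)
    return abs(ap @ n) / np.linalg.norm(n)


def distance_to_surface(vertices, triangles, point):
    best = np.inf
    for tri in triangles:
        d = point_triangle_distance(np.asarray(point, float),
                                    vertices[tri[0]], vertices[tri[1]],
                                    vertices[tri[2]])
        best = min(best, d)
        if best == 0.0:
            break
    return best
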