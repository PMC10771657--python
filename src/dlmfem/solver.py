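"""Static finite-element contact solver.

Linear TET4 (C3D4) elements with small-strain kinematics for the deformable
tissues, rigid bones reduced to reference-point degrees of freedom, ligament
fibers with finite stretch, and frictionless node-to-surface penalty contact
with pairing fixed at initialization (limited sliding).  The tibia-fibula is
fully fixed; the femur keeps medial-lateral translation, axial translation
and varus/valgus rotation free (tx, tz, ry in the package's frame) and
carries the 1150 N compressive stance load.

The bulk response is linear, so the only nonlinearities are the contact
active set and the tension-only / Neo-Hookean fibers; the load is ramped in
increments and each increment solved by Newton iteration with a consistent
tangent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import meshing
from .geometry import KneeGeometry, MeshSizes
from .materials import (IsotropicElastic, LinearFiber, NeoHookeanParams,
                        TransverselyIsotropicElastic, compute_fiber_frames,
                        stiffness_isotropic, stiffness_trans_iso_batch)

logger = logging.getLogger("dlmfem")

_VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))


class AssemblyError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

@dataclass
class TetraMesh:
    nodes: np.ndarray                 # (N, 3)
    tets: np.ndarray                  # (M, 4)
    region: np.ndarray                # (M,) region tag per element
    node_sets: dict = field(default_factory=dict)
    surfaces: dict = field(default_factory=dict)   # name -> (t, 3) triangles
    geometry: KneeGeometry | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def volumes(self) -> np.ndarray:
        return meshing.tet_volumes(self.nodes, self.tets)

    def quality_min_aspect(self) -> float:
        """Minimum (normalized) ratio of inradius-like measure; crude floor check."""
        v = self.volumes()
        coords = self.nodes[self.tets]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        lmax = np.zeros(len(self.tets))
        for i, j in pairs:
            lmax = np.maximum(lmax,
                              np.linalg.norm(coords[:, i] - coords[:, j], axis=1))
        return float((v / lmax ** 3).min() * 6.0 * math.sqrt(2.0))


def box_mesh(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
             region: str = "block") -> TetraMesh:
    """Structured box mesh from (possibly graded) coordinate arrays."""
    grid = meshing.rect_grid(np.asarray(xs, float), np.asarray(ys, float))
    zs = np.asarray(zs, float)
    frac = (zs - zs[0]) / (zs[-1] - zs[0])
    n2 = len(grid.points)
    block = meshing.extrude(grid, np.full(n2, zs[0]), np.full(n2, zs[-1]),
                            len(zs) - 1, layer_fractions=frac)
    mesh = TetraMesh(nodes=block.nodes, tets=block.tets,
                     region=np.full(len(block.tets), region, dtype="<U40"))
    mesh.node_sets["bottom"] = block.bottom_nodes
    mesh.node_sets["top"] = block.top_nodes
    mesh.surfaces["top"] = block.top_tris
    mesh.surfaces["bottom"] = block.bottom_tris
    return mesh


def mesh_solids(geometry: KneeGeometry,
                sizes: MeshSizes | None = None) -> TetraMesh:
    """Conforming tet mesh of all deformable solids, with the node sets and
    surface triangulations the contact and boundary conditions need.

    Bones stay rigid surfaces; their discretization never enters the solve.
    """
    from .geometry import LayerParam, MeniscusParam, mesh_cartilage, mesh_meniscus

    sizes = sizes or MeshSizes()
    all_nodes, all_tets, all_regions = [], [], []
    node_sets: dict[str, list] = {"fixed": [], "femur_bonded": []}
    surfaces: dict[str, np.ndarray] = {}
    offset = 0
    for solid in geometry.solids:
        param = solid.parametric
        if solid.block is not None:
            block = solid.block        # mesh-level shaping (smoothed resections)
        elif isinstance(param, LayerParam):
            block = mesh_cartilage(param, sizes)
        elif isinstance(param, MeniscusParam):
            block = mesh_meniscus(param, sizes)
        else:
            raise AssemblyError(f"solid {solid.tag} has no parametric description")
        tag = solid.tag
        all_nodes.append(block.nodes)
        all_tets.append(block.tets + offset)
        all_regions.append(np.full(len(block.tets), tag, dtype="<U40"))
        surfaces[f"{tag}_top"] = block.top_tris + offset
        surfaces[f"{tag}_bottom"] = block.bottom_tris + offset
        node_sets[f"{tag}_top_nodes"] = block.top_nodes + offset
        node_sets[f"{tag}_bottom_nodes"] = block.bottom_nodes + offset
        if tag.startswith("femoral_cartilage"):
            node_sets["femur_bonded"].append(block.top_nodes + offset)
        elif tag.startswith("tibial_cartilage"):
            node_sets["fixed"].append(block.bottom_nodes + offset)
        elif tag.startswith("meniscus"):
            # root/capsule attachment ring (inferior outer rim); anchored by
            # compliant ground springs rather than fixed — a rigid clamp
            # concentrates spurious bending stress at the boundary
            node_sets[f"{tag}_root_nodes"] = block.outer_rim_nodes + offset
        offset += len(block.nodes)

    mesh = TetraMesh(
        nodes=np.vstack(all_nodes), tets=np.vstack(all_tets),
        region=np.concatenate(all_regions), surfaces=surfaces,
        geometry=geometry)
    mesh.node_sets = {k: (np.unique(np.concatenate(v)) if isinstance(v, list)
                          else v)
                      for k, v in node_sets.items()}
    if (mesh.volumes() <= 0).any():
        raise AssemblyError("mesh contains non-positive tet volumes")
    return mesh


# ---------------------------------------------------------------------------
# Element stiffness / assembly
# ---------------------------------------------------------------------------

def element_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Shape-function gradients and volumes for all TET4 elements."""
    coords = nodes[tets]                          # (M, 4, 3)
    A = np.concatenate([np.ones((len(tets), 4, 1)), coords], axis=2)
    Ainv = np.linalg.inv(A)
    grads = Ainv[:, 1:, :].transpose(0, 2, 1)     # (M, 4, 3): dN_a/dx_i
    vol = np.abs(np.linalg.det(A)) / 6.0
    return grads, vol


def element_b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, Voigt order (11,22,33,23,13,12),
    engineering shear.  Shape (M, 6, 12); dof order (node, xyz)."""
    M = len(grads)
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 1] = gz
        B[:, 3, c + 2] = gy
        B[:, 4, c + 0] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 0] = gy
        B[:, 5, c + 1] = gx
    return B


def element_stiffness_tensors(mesh: TetraMesh, materials: dict) -> np.ndarray:
    """Per-element 6x6 stiffness (global axes); meniscus elements get the
    transversely isotropic tensor rotated into their circumferential frame."""
    M = len(mesh.tets)
    C = np.empty((M, 6, 6))
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    for tag in np.unique(mesh.region):
        if tag not in materials:
            raise AssemblyError(f"region '{tag}' has no material card")
        mat = materials[tag]
        idx = np.where(mesh.region == tag)[0]
        if isinstance(mat, IsotropicElastic):
            C[idx] = stiffness_isotropic(mat)
        elif isinstance(mat, TransverselyIsotropicElastic):
            margin = _outer_margin_polygon(mesh, tag)
            frames = compute_fiber_frames(centroids[idx], margin)
            C[idx] = stiffness_trans_iso_batch(mat, frames)
        else:
            raise AssemblyError(f"unsupported bulk material for region {tag}")
    return C


def _outer_margin_polygon(mesh: TetraMesh, tag: str) -> np.ndarray:
    """Outer margin of a meniscus region in plan view."""
    if mesh.geometry is not None:
        side = "lateral" if tag.endswith("lateral") else "medial"
        comp = mesh.geometry.compartments[side]
        th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        return np.column_stack([comp.xc + comp.a * np.cos(th),
                                comp.yc + comp.b * np.sin(th)])
    pts = mesh.nodes[np.unique(mesh.tets[mesh.region == tag])][:, :2]
    from scipy.spatial import ConvexHull
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def assemble(mesh: TetraMesh, materials: dict):
    """Global stiffness (3N x 3N CSR) plus element data for stress recovery.

    Deterministic: fixed element ordering, duplicate assembly is bit-identical.
    """
    grads, vol = element_gradients(mesh.nodes, mesh.tets)
    B = element_b_matrices(grads)
    C = element_stiffness_tensors(mesh, materials)
    Ke = np.einsum("mji,mjk,mkl,m->mil", B, C, B, vol, optimize=True)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(len(mesh.tets), 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)).tocsr()
    K.sum_duplicates()
    return K, {"B": B, "C": C, "vol": vol, "grads": grads}


# ---------------------------------------------------------------------------
# Rigid bodies, contact, load case
# ---------------------------------------------------------------------------

@dataclass
class RigidBody:
    name: str
    reference: np.ndarray
    free: tuple = ()                   # subset of (tx, ty, tz, rx, ry, rz)
    load: dict = field(default_factory=dict)    # free-dof label -> force
    bonded_set: str | None = None      # mesh node set rigidly attached


def _rigid_columns(ref: np.ndarray, X: np.ndarray, labels) -> np.ndarray:
    """(npoints, 3, nq) linearized rigid-motion map u = A q."""
    r = X - ref
    cols = []
    zeros = np.zeros(len(X))
    ones = np.ones(len(X))
    for lab in labels:
        if lab == "tx":
            cols.append(np.stack([ones, zeros, zeros], axis=1))
        elif lab == "ty":
            cols.append(np.stack([zeros, ones, zeros], axis=1))
        elif lab == "tz":
            cols.append(np.stack([zeros, zeros, ones], axis=1))
        elif lab == "rx":
            cols.append(np.stack([zeros, -r[:, 2], r[:, 1]], axis=1))
        elif lab == "ry":
            cols.append(np.stack([r[:, 2], zeros, -r[:, 0]], axis=1))
        elif lab == "rz":
            cols.append(np.stack([-r[:, 1], r[:, 0], zeros], axis=1))
        else:
            raise ValueError(lab)
    return np.stack(cols, axis=2)


@dataclass
class ContactPairSet:
    """Node-to-surface pairs with pairing fixed at initialization."""
    name: str
    followers: np.ndarray         # (F,) node ids
    tri_nodes: np.ndarray         # (F, 3) target node ids
    weights: np.ndarray           # (F, 3) barycentric weights at pairing
    normals: np.ndarray           # (F, 3) target normals toward the follower
    g0: np.ndarray                # (F,) initial gaps (>= 0)
    areas: np.ndarray             # (F,) follower tributary areas
    penalty: float                # N/mm^3


@dataclass
class AnalyticContact:
    """Contact of deformable nodes against an analytic rigid surface that may
    ride on a rigid body's translational DOFs (sphere or plane)."""
    name: str
    kind: str                     # 'sphere' | 'plane'
    nodes: np.ndarray
    areas: np.ndarray
    penalty: float
    body: str | None = None
    center: np.ndarray | None = None      # sphere
    radius: float = 0.0
    origin: np.ndarray | None = None      # plane
    normal: np.ndarray | None = None      # admissible side: n.(p - o) >= 0


@dataclass
class LoadCase:
    increments: int = 10
    tolerance: float = 1e-6
    max_iterations: int = 50
    max_penetration: float = 0.02          # mm
    penalty_escalations: int = 3
    max_step: float = 0.5                  # Newton step cap, mm (keeps rigid
                                           # bodies from overshooting contact)


@dataclass
class FiberBundle:
    body: str                     # rigid body carrying the moving end
    attach_points: np.ndarray     # (nf, 3) reference positions on the body
    fixed_points: np.ndarray      # (nf, 3)
    areas: np.ndarray             # (nf,)
    material: object              # NeoHookeanParams | LinearFiber
    name: str = ""


@dataclass
class SolutionState:
    mesh: TetraMesh
    displacements: np.ndarray     # (N, 3)
    rigid_dofs: dict              # body name -> {label: value}
    contact_forces: dict          # pair-set name -> total normal force (N)
    contact_penetration: dict     # pair-set name -> max penetration (mm)
    reactions: np.ndarray         # (N, 3) support reactions at fixed nodes
    converged: bool
    log: list
    applied_load: float


def pair_contact(mesh: TetraMesh, follower_set: str, target_surface: str,
                 follower_surface: str, penalty: float,
                 name: str | None = None) -> ContactPairSet | None:
    """Pair each follower node with the target triangle under it (plan view)."""
    followers = mesh.node_sets[follower_set]
    tris = mesh.surfaces[target_surface]
    P = mesh.nodes[followers]
    T1, T2, T3 = (mesh.nodes[tris[:, k]] for k in range(3))

    # plan-view barycentric membership, all followers x all triangles
    d = ((T2[:, 0] - T1[:, 0]) * (T3[:, 1] - T1[:, 1])
         - (T3[:, 0] - T1[:, 0]) * (T2[:, 1] - T1[:, 1]))
    px = P[:, 0][:, None]
    py = P[:, 1][:, None]
    w1 = ((T2[:, 0] - px) * (T3[:, 1] - py)
          - (T3[:, 0] - px) * (T2[:, 1] - py)) / d
    w2 = ((T3[:, 0] - px) * (T1[:, 1] - py)
          - (T1[:, 0] - px) * (T3[:, 1] - py)) / d
    w3 = 1.0 - w1 - w2
    ok = (w1 >= -1e-9) & (w2 >= -1e-9) & (w3 >= -1e-9)
    hit = ok.any(axis=1)
    if not hit.any():
        return None
    first = np.argmax(ok, axis=1)
    sel_f = np.where(hit)[0]
    sel_t = first[hit]
    sel_w = np.column_stack([w1[sel_f, sel_t], w2[sel_f, sel_t],
                             w3[sel_f, sel_t]])
    fi = followers[np.asarray(sel_f)]
    tsel = tris[np.asarray(sel_t)]
    W = np.asarray(sel_w)
    n = np.cross(mesh.nodes[tsel[:, 1]] - mesh.nodes[tsel[:, 0]],
                 mesh.nodes[tsel[:, 2]] - mesh.nodes[tsel[:, 0]])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    proj = np.einsum("fk,fkd->fd", W, mesh.nodes[tsel])
    gap_vec = mesh.nodes[fi] - proj
    flip = np.einsum("fd,fd->f", n, gap_vec) < 0
    n[flip] *= -1.0
    g0 = np.einsum("fd,fd->f", n, gap_vec)
    trib = meshing.node_tributary_areas(
        mesh.nodes, mesh.surfaces[follower_surface])
    return ContactPairSet(
        name=name or f"{follower_set}->{target_surface}",
        followers=fi, tri_nodes=tsel, weights=W, normals=n, g0=g0,
        areas=trib[fi], penalty=penalty)


def default_penalty(E_target: float, h: float, factor: float = 50.0) -> float:
    """Spec'd default: 50 x target modulus / local element size (N/mm^3)."""
    return factor * E_target / h


# ---------------------------------------------------------------------------
# Static solve
# ---------------------------------------------------------------------------

class StaticProblem:
    """Reduced-coordinate static problem: free nodal DOFs + rigid-body DOFs."""

    def __init__(self, mesh: TetraMesh, K: sp.csr_matrix,
                 rigid_bodies: list[RigidBody],
                 contacts: list[ContactPairSet],
                 analytic_contacts: list[AnalyticContact] = (),
                 fibers: list[FiberBundle] = (),
                 fixed_set: str = "fixed",
                 prescribed: np.ndarray | None = None,
                 nodal_loads: np.ndarray | None = None,
                 stabilization: float = 1e-3,
                 ground_springs: tuple | None = None):
        self.mesh = mesh
        self.K = K
        self.bodies = list(rigid_bodies)
        self.contacts = [c for c in contacts if c is not None]
        self.analytic = list(analytic_contacts)
        self.fibers = list(fibers)
        self.stab = stabilization
        N = mesh.n_nodes
        self.prescribed = (np.zeros(3 * N) if prescribed is None
                           else prescribed.ravel().copy())
        self.F_nodes = (np.zeros(3 * N) if nodal_loads is None
                        else nodal_loads.ravel().copy())

        fixed = np.zeros(N, dtype=bool)
        if fixed_set in mesh.node_sets:
            fixed[mesh.node_sets[fixed_set]] = True
        bonded = np.full(N, -1, dtype=np.int64)
        for bi, body in enumerate(self.bodies):
            if body.bonded_set:
                ids = mesh.node_sets[body.bonded_set]
                bonded[ids] = bi
        if np.any(fixed & (bonded >= 0)):
            raise AssemblyError("a node cannot be both fixed and rigid-bonded")
        self.fixed_nodes = fixed
        self.bonded = bonded

        # reduced dof numbering
        free_nodes = np.where(~fixed & (bonded < 0))[0]
        self.free_nodes = free_nodes
        self.n_free = 3 * len(free_nodes)
        self.q_offset = {}
        nq = 0
        for body in self.bodies:
            self.q_offset[body.name] = self.n_free + nq
            nq += len(body.free)
        self.n_red = self.n_free + nq

        # transformation T: full (3N) <- reduced
        rows, cols, vals = [], [], []
        for k, nid in enumerate(free_nodes):
            for d in range(3):
                rows.append(3 * nid + d)
                cols.append(3 * k + d)
                vals.append(1.0)
        for bi, body in enumerate(self.bodies):
            if not body.bonded_set or not body.free:
                continue
            ids = mesh.node_sets[body.bonded_set]
            A = _rigid_columns(np.asarray(body.reference, float),
                               mesh.nodes[ids], body.free)
            off = self.q_offset[body.name]
            for i, nid in enumerate(ids):
                for d in range(3):
                    for j in range(len(body.free)):
                        if A[i, d, j] != 0.0:
                            rows.append(3 * nid + d)
                            cols.append(off + j)
                            vals.append(A[i, d, j])
        self.T = sp.coo_matrix((vals, (rows, cols)),
                               shape=(3 * N, self.n_red)).tocsr()
        # compliant anchors (e.g. meniscal root/capsule attachments):
        # isotropic springs to ground at the given nodes, N/mm per node
        self.spring_nodes = np.empty(0, dtype=np.int64)
        self.spring_k = np.empty(0)
        K_springs = None
        if ground_springs is not None:
            nodes_s, k_s = ground_springs
            self.spring_nodes = np.asarray(nodes_s, dtype=np.int64)
            self.spring_k = np.broadcast_to(
                np.asarray(k_s, dtype=float), self.spring_nodes.shape).copy()
            dof = (3 * self.spring_nodes[:, None]
                   + np.arange(3)).ravel()
            kv = np.repeat(self.spring_k, 3)
            K_springs = sp.coo_matrix((kv, (dof, dof)),
                                      shape=(3 * N, 3 * N)).tocsr()
        K_eff = K if K_springs is None else K + K_springs
        self.K_springs = K_springs
        self.K_red = (self.T.T @ (K_eff @ self.T)).tocsr()

        # reduced external load
        self.F_red = self.T.T @ self.F_nodes
        for body in self.bodies:
            off = self.q_offset[body.name]
            for j, lab in enumerate(body.free):
                self.F_red[off + j] += body.load.get(lab, 0.0)
        self.F_fixed_part = self.K @ self.prescribed  # constant contribution

        # constant contact jacobians for deformable-deformable pairs
        self._Dg = []
        self._G_red = []
        for c in self.contacts:
            rows, cols, vals = [], [], []
            for i in range(len(c.followers)):
                f = c.followers[i]
                for d in range(3):
                    rows.append(i)
                    cols.append(3 * f + d)
                    vals.append(c.normals[i, d])
                for k in range(3):
                    t = c.tri_nodes[i, k]
                    for d in range(3):
                        rows.append(i)
                        cols.append(3 * t + d)
                        vals.append(-c.weights[i, k] * c.normals[i, d])
            Dg = sp.coo_matrix((vals, (rows, cols)),
                               shape=(len(c.followers), 3 * N)).tocsr()
            self._Dg.append(Dg)
            self._G_red.append((Dg @ self.T).tocsr())

        # fiber precomputation
        self._fiber_data = []
        for fb in self.fibers:
            body = next(b for b in self.bodies if b.name == fb.body)
            A = _rigid_columns(np.asarray(body.reference, float),
                               fb.attach_points, body.free)
            L0 = np.linalg.norm(fb.attach_points - fb.fixed_points, axis=1)
            self._fiber_data.append((fb, body, A, L0))

    # -- helpers -----------------------------------------------------------

    def full_displacement(self, x: np.ndarray) -> np.ndarray:
        return self.T @ x + self.prescribed

    def body_q(self, x: np.ndarray, body: RigidBody) -> np.ndarray:
        off = self.q_offset[body.name]
        return x[off:off + len(body.free)]

    def _fiber_force_tangent(self, x):
        R = np.zeros(self.n_red)
        triplets = []
        for fb, body, A, L0 in self._fiber_data:
            off = self.q_offset[body.name]
            nq = len(body.free)
            q = x[off:off + nq]
            ends = fb.attach_points + np.einsum("idj,j->id", A, q)
            d = ends - fb.fixed_points
            l = np.linalg.norm(d, axis=1)
            lam = l / L0
            for i in range(len(l)):
                mat = fb.material
                if isinstance(mat, NeoHookeanParams):
                    active = (not mat.tension_only) or lam[i] >= 1.0 - 1e-12
                    Nf = (0.0 if not active
                          else 2 * mat.C1 * fb.areas[i] * (lam[i] - lam[i] ** -2))
                    dN = (0.0 if not active
                          else 2 * mat.C1 * fb.areas[i] * (1 + 2 * lam[i] ** -3))
                elif isinstance(mat, LinearFiber):
                    active = (not mat.tension_only) or lam[i] >= 1.0 - 1e-12
                    Nf = 0.0 if not active else mat.E * fb.areas[i] * (lam[i] - 1)
                    dN = 0.0 if not active else mat.E * fb.areas[i]
                else:
                    raise AssemblyError("unsupported fiber material")
                if not active:
                    continue
                u = d[i] / l[i]
                Ai = A[i]                      # (3, nq)
                R[off:off + nq] += Ai.T @ (Nf * u)
                kmat = (dN / L0[i]) * np.outer(u, u)
                if l[i] > 0:
                    kmat += (Nf / l[i]) * (np.eye(3) - np.outer(u, u))
                kq = Ai.T @ kmat @ Ai
                for a in range(nq):
                    for b in range(nq):
                        triplets.append((off + a, off + b, kq[a, b]))
        return R, triplets

    def _analytic_contact(self, x, scale_pen):
        """Residual, stiffness triplets and full-space nodal forces."""
        R = np.zeros(self.n_red)
        F_full = np.zeros(3 * self.mesh.n_nodes)
        triplets = []
        max_pen = {}
        forces = {}
        U = self.full_displacement(x).reshape(-1, 3)
        node_red = {}
        for k, nid in enumerate(self.free_nodes):
            node_red[nid] = 3 * k
        for ac in self.analytic:
            pen_k = ac.penalty * scale_pen.get(ac.name, 1.0)
            body = (next(b for b in self.bodies if b.name == ac.body)
                    if ac.body else None)
            qoff = self.q_offset.get(ac.body, None)
            q = (x[qoff:qoff + len(body.free)] if body is not None
                 else np.zeros(0))
            shift = np.zeros(3)
            if body is not None:
                for j, lab in enumerate(body.free):
                    if lab == "tx":
                        shift[0] += q[j]
                    elif lab == "ty":
                        shift[1] += q[j]
                    elif lab == "tz":
                        shift[2] += q[j]
            worst = 0.0
            ftot = 0.0
            for i, nid in enumerate(ac.nodes):
                p = self.mesh.nodes[nid] + U[nid]
                if ac.kind == "sphere":
                    c = ac.center + shift
                    dvec = p - c
                    dist = np.linalg.norm(dvec)
                    g = dist - ac.radius
                    u = dvec / dist
                    dg_du = u
                    dg_dq = -u
                else:
                    o = ac.origin + shift
                    g = float(np.dot(ac.normal, p - o))
                    dg_du = ac.normal
                    dg_dq = -ac.normal
                if g >= 0:
                    continue
                worst = max(worst, -g)
                kappa = pen_k * ac.areas[i]
                fmag = kappa * g                 # < 0
                ftot += -fmag
                # full-space nodal force (for reactions)
                F_full[3 * nid:3 * nid + 3] += fmag * dg_du
                # reduced residual
                entries = []
                if nid in node_red:
                    base = node_red[nid]
                    for d in range(3):
                        entries.append((base + d, dg_du[d]))
                if body is not None:
                    for j, lab in enumerate(body.free):
                        if lab in ("tx", "ty", "tz"):
                            comp = {"tx": 0, "ty": 1, "tz": 2}[lab]
                            entries.append((qoff + j, dg_dq[comp]))
                for idx, val in entries:
                    R[idx] += fmag * val
                for idx1, v1 in entries:
                    for idx2, v2 in entries:
                        triplets.append((idx1, idx2, kappa * v1 * v2))
            max_pen[ac.name] = worst
            forces[ac.name] = ftot
        return R, triplets, F_full, max_pen, forces


def solve_static(problem: StaticProblem,
                 load: LoadCase | None = None) -> SolutionState:
    """Incremental load ramp with Newton iterations; penalty escalation if the
    converged state still violates the penetration limit."""
    load = load or LoadCase()
    scale_pen: dict[str, float] = {}
    log: list[str] = []

    for attempt in range(load.penalty_escalations + 1):
        x, final = _solve_ramp(problem, load, scale_pen, log)
        worst = max(final["max_pen"].values()) if final["max_pen"] else 0.0
        if worst <= load.max_penetration:
            break
        for name, pen in final["max_pen"].items():
            if pen > load.max_penetration:
                scale_pen[name] = scale_pen.get(name, 1.0) * 10.0
                log.append(f"penalty escalation x10 on '{name}' "
                           f"(penetration {pen:.4f} mm)")
    else:
        raise ConvergenceError(
            f"penetration {worst:.4f} mm exceeds limit after escalations")

    U = problem.full_displacement(x).reshape(-1, 3)
    # support reactions: internal force minus external at fixed dofs, plus
    # the force each ground spring transmits to its anchor
    R_full = (problem.K @ problem.full_displacement(x)
              + final["F_contact_full"] - problem.F_nodes)
    reactions = R_full.reshape(-1, 3).copy()
    reactions[~problem.fixed_nodes] = 0.0
    if len(problem.spring_nodes):
        # spring support force on the structure is -k u (same sign
        # convention as the fixed-dof reactions above)
        reactions[problem.spring_nodes] -= \
            problem.spring_k[:, None] * U[problem.spring_nodes]
    rigid = {}
    for body in problem.bodies:
        qv = problem.body_q(x, body)
        rigid[body.name] = {lab: float(qv[j]) for j, lab in enumerate(body.free)}
    applied = float(np.linalg.norm(problem.F_red))
    return SolutionState(
        mesh=problem.mesh, displacements=U, rigid_dofs=rigid,
        contact_forces=final["forces"], contact_penetration=final["max_pen"],
        reactions=reactions, converged=True, log=log, applied_load=applied)


def _solve_ramp(problem: StaticProblem, load: LoadCase,
                scale_pen: dict, log: list):
    x = np.zeros(problem.n_red)
    stab_idx = np.arange(problem.n_free, problem.n_red)
    Kst = sp.coo_matrix(
        (np.full(len(stab_idx), problem.stab), (stab_idx, stab_idx)),
        shape=(problem.n_red, problem.n_red)).tocsr()
    # tangent factorization cache: the tangent is SPD, so a symmetric-mode
    # factorization with diagonal pivoting is stable and cheap; it is reused
    # as a CG preconditioner across iterations (the active set changes only
    # slightly) and refreshed whenever CG stalls
    cache = {"lu": None}

    def factor(Kt):
        A = Kt.tocsc()
        A.sum_duplicates()
        try:
            return spla.splu(A, permc_spec="MMD_AT_PLUS_A",
                             options=dict(SymmetricMode=True,
                                          DiagPivotThresh=0.0))
        except RuntimeError:      # unexpected zero pivot: robust fallback
            return spla.splu(A, permc_spec="COLAMD")

    def tangent_solve(Kt, rhs):
        if cache["lu"] is None:
            cache["lu"] = factor(Kt)
            return cache["lu"].solve(rhs)
        M = spla.LinearOperator((problem.n_red, problem.n_red),
                                cache["lu"].solve)
        sol, info = spla.cg(Kt.tocsr(), rhs, M=M, rtol=1e-8, atol=0.0,
                            maxiter=60)
        if info != 0:
            cache["lu"] = factor(Kt)
            sol = cache["lu"].solve(rhs)
        return sol

    final = None
    for inc in range(1, load.increments + 1):
        s = inc / load.increments
        ref = max(1.0, s * np.linalg.norm(problem.F_red)
                  + np.linalg.norm(problem.T.T @ problem.F_fixed_part))
        converged = False
        for it in range(load.max_iterations):
            R = problem.K_red @ x + problem.T.T @ problem.F_fixed_part \
                - s * problem.F_red
            R[stab_idx] += problem.stab * x[stab_idx]
            Kt = problem.K_red + Kst
            F_contact_full = np.zeros(3 * problem.mesh.n_nodes)
            forces = {}
            max_pen = {}
            # deformable-deformable pairs (linear gap)
            Ufull = problem.full_displacement(x)
            for c, Dg, G in zip(problem.contacts, problem._Dg, problem._G_red):
                pen = c.penalty * scale_pen.get(c.name, 1.0)
                g = c.g0 + Dg @ Ufull
                act = g < 0
                kappa = pen * c.areas
                fmag = np.where(act, kappa * g, 0.0)
                R += G.T @ fmag
                F_contact_full += Dg.T @ fmag
                if act.any():
                    Ga = G[act]
                    Kt = Kt + Ga.T @ sp.diags(kappa[act]) @ Ga
                forces[c.name] = float(-fmag.sum())
                max_pen[c.name] = float(-g[act].min()) if act.any() else 0.0
            # analytic rigid-surface contacts
            Ra, trip, Fa_full, pen_a, forces_a = problem._analytic_contact(
                x, scale_pen)
            R += Ra
            F_contact_full += Fa_full
            forces.update(forces_a)
            max_pen.update(pen_a)
            # fibers
            Rf, ftrip = problem._fiber_force_tangent(x)
            R += Rf
            trip = trip + ftrip
            if trip:
                ti, tj, tv = zip(*trip)
                Kt = Kt + sp.coo_matrix(
                    (tv, (ti, tj)),
                    shape=(problem.n_red, problem.n_red)).tocsr()
            rnorm = np.linalg.norm(R)
            if rnorm < load.tolerance * ref:
                converged = True
                final = {"forces": forces, "max_pen": max_pen,
                         "F_contact_full": F_contact_full}
                break
            dx = tangent_solve(Kt, -R)
            step = np.abs(dx).max()
            if step > load.max_step:
                dx *= load.max_step / step
            x = x + dx
        if not converged:
            raise ConvergenceError(
                f"increment {inc}/{load.increments} did not converge "
                f"(residual {rnorm:.3e}, penetrations {max_pen})")
        log.append(f"increment {inc}: converged in {it + 1} iterations")
    return x, final


def contact_report(state: SolutionState) -> dict:
    """Per-pair normal force, penetration, and the tibial-side balance."""
    total = sum(state.contact_forces.values())
    rz = float(state.reactions[:, 2].sum())
    return {
        "pair_forces_N": dict(state.contact_forces),
        "max_penetration_mm": dict(state.contact_penetration),
        "total_contact_force_N": total,
        "tibial_reaction_N": rz,
    }


# ---------------------------------------------------------------------------
# Verification benchmarks (independent closed-form oracles)
# ---------------------------------------------------------------------------

def run_patch_test(n: int = 3) -> float:
    """Constant-strain patch test on a unit cube; returns max relative
    deviation of element stresses from the exact constant field."""
    from .postprocess import recover_stresses

    g = np.linspace(0.0, 1.0, n + 1)
    mesh = box_mesh(g, g, g)
    mat = {"block": IsotropicElastic(E=15.0, nu=0.3)}
    K, data = assemble(mesh, mat)
    A = np.array([[1e-3, 4e-4, -2e-4],
                  [4e-4, -5e-4, 3e-4],
                  [-2e-4, 3e-4, 8e-4]])
    u_aff = mesh.nodes @ A.T
    on_boundary = np.any((mesh.nodes <= 0) | (mesh.nodes >= 1), axis=1)
    prescribed = np.zeros((mesh.n_nodes, 3))
    prescribed[on_boundary] = u_aff[on_boundary]
    mesh.node_sets["fixed"] = np.where(on_boundary)[0]
    prob = StaticProblem(mesh, K, [], [], prescribed=prescribed.ravel(),
                         stabilization=0.0)
    state = solve_static(prob, LoadCase(increments=1))
    field_ = recover_stresses(state, mesh, data)
    sigma = field_.tensors
    C = stiffness_isotropic(mat["block"])
    eps = np.array([A[0, 0], A[1, 1], A[2, 2],
                    2 * A[1, 2], 2 * A[0, 2], 2 * A[0, 1]])
    sv = C @ eps
    exact = np.array([[sv[0], sv[5], sv[4]],
                      [sv[5], sv[1], sv[3]],
                      [sv[4], sv[3], sv[2]]])
    err = np.abs(sigma - exact).max() / np.abs(exact).max()
    return float(err)


def run_uniaxial_block(pressure: float = 1.0, E: float = 15.0) -> dict:
    """Block squeezed by a rigid plate: axial strain must equal p/E (nu=0)."""
    g = np.linspace(0.0, 10.0, 5)
    zs = np.linspace(0.0, 10.0, 5)
    mesh = box_mesh(g, g, zs)
    mesh.node_sets["fixed"] = mesh.node_sets["bottom"]
    mat = {"block": IsotropicElastic(E=E, nu=0.0)}
    K, _ = assemble(mesh, mat)
    area = 100.0
    F = pressure * area
    plate = RigidBody(name="plate", reference=np.array([5.0, 5.0, 10.0]),
                      free=("tz",), load={"tz": -F})
    top = mesh.node_sets["top"]
    trib = meshing.node_tributary_areas(mesh.nodes, mesh.surfaces["top"])
    ac = AnalyticContact(
        name="plate", kind="plane", nodes=top, areas=trib[top],
        penalty=default_penalty(E, 2.5), body="plate",
        origin=np.array([0.0, 0.0, 10.0]), normal=np.array([0.0, 0.0, -1.0]))
    prob = StaticProblem(mesh, K, [plate], [], analytic_contacts=[ac])
    state = solve_static(prob, LoadCase(increments=2))
    uz = state.displacements[top, 2].mean()
    strain = -uz / 10.0
    return {"strain": float(strain), "expected": pressure / E,
            "rel_err": float(abs(strain - pressure / E) / (pressure / E))}


def run_hertz_benchmark(force: float = 100.0, radius: float = 20.0,
                        E: float = 15.0, nu: float = 0.3) -> dict:
    """Rigid sphere pressed into an elastic block; compares the peak contact
    pressure with the Hertz closed form p0 = (6 F E*^2 / (pi^3 R^2))^(1/3).

    The peak is estimated from the discrete penalty tractions by linear
    regression of p^2 on r^2 over the active nodes (Hertz profile:
    p^2 = p0^2 (1 - r^2/a^2) is linear in r^2), which filters the apex
    overshoot of the raw nodal maximum; both values are reported.
    """
    Estar = E / (1 - nu ** 2)
    a_hertz = (3 * force * radius / (4 * Estar)) ** (1.0 / 3.0)
    p0 = (6 * force * Estar ** 2 / (np.pi ** 3 * radius ** 2)) ** (1.0 / 3.0)

    fine = np.arange(-6.0, 6.0 + 1e-9, 0.75)
    outer = np.array([-30.0, -21.0, -14.0, -9.5])
    xs = np.concatenate([outer, fine, -outer[::-1]])
    zt = np.array([0.0, 0.5, 1.1, 1.9, 3.0, 4.4, 6.2, 8.6, 12.0, 17.0, 24.0,
                   30.0])
    zs = 30.0 - zt[::-1]
    mesh = box_mesh(xs, xs, zs)
    mesh.node_sets["fixed"] = mesh.node_sets["bottom"]
    mat = {"block": IsotropicElastic(E=E, nu=nu)}
    K, _ = assemble(mesh, mat)
    sphere_body = RigidBody(name="indenter",
                            reference=np.array([0.0, 0.0, 30.0 + radius]),
                            free=("tz",), load={"tz": -force})
    top = mesh.node_sets["top"]
    trib = meshing.node_tributary_areas(mesh.nodes, mesh.surfaces["top"])
    ac = AnalyticContact(
        name="sphere", kind="sphere", nodes=top, areas=trib[top],
        penalty=default_penalty(E, 0.75, factor=200.0), body="indenter",
        center=np.array([0.0, 0.0, 30.0 + radius]), radius=radius)
    prob = StaticProblem(mesh, K, [sphere_body], [], analytic_contacts=[ac])
    state = solve_static(prob, LoadCase(increments=2, max_penetration=0.05))

    # nodal contact pressure from the penalty tractions
    U = state.displacements
    c = ac.center + np.array([0.0, 0.0, state.rigid_dofs["indenter"]["tz"]])
    p = mesh.nodes[top] + U[top]
    gap = np.linalg.norm(p - c, axis=1) - radius
    pressure = np.where(gap < 0, -ac.penalty * gap, 0.0)
    # peak via the Hertz-profile linearization p^2 = c0 + c1 r^2
    r2 = mesh.nodes[top, 0] ** 2 + mesh.nodes[top, 1] ** 2
    act = pressure > 0
    A = np.column_stack([np.ones(int(act.sum())), r2[act]])
    coef, *_ = np.linalg.lstsq(A, pressure[act] ** 2, rcond=None)
    peak = float(np.sqrt(max(coef[0], 0.0)))
    a_fem = float(np.sqrt(-coef[0] / coef[1])) if coef[1] < 0 else float("nan")
    return {"p0_fem": peak, "p0_node_max": float(pressure.max()),
            "p0_hertz": float(p0),
            "contact_radius_fem": a_fem,
            "contact_radius_hertz": float(a_hertz),
            "rel_err": float(abs(peak - p0) / p0),
            "total_force": float(sum(state.contact_forces.values()))}
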