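"""Constitutive models.

Bone is rigid.  Articular cartilage and the collateral/patellar ligaments are
isotropic linear elastic (E = 15 / 60 MPa, nu = 0.3).  The meniscus is
transversely isotropic with the circumferential direction as the stiff axis
(E_circ = 140 MPa) and the radial-axial plane as the isotropy plane
(E = 20 MPa; in-plane nu = 0.2, out-of-plane nu = 0.3) — circumferential
collagen fibers resist hoop tension and outward extrusion.  The cruciate
ligaments are Neo-Hookean hyperelastic (ACL: C1 = 5.08 MPa, D1 = 0.00683
MPa^-1; PCL: C1 = 6.06, D1 = 0.0041).

Voigt order throughout: (11, 22, 33, 23, 13, 12); engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MaterialParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Isotropic linear elasticity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotropicElastic:
    E: float
    nu: float

    def validate(self) -> None:
        if self.E <= 0:
            raise MaterialParameterError("E must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise MaterialParameterError("nu must lie in (-1, 0.5)")


def stiffness_isotropic(mat: IsotropicElastic) -> np.ndarray:
    mat.validate()
    E, nu = mat.E, mat.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


# ---------------------------------------------------------------------------
# Transverse isotropy (fiber axis = local direction 1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransverselyIsotropicElastic:
    E_circ: float = 140.0
    E_plane: float = 20.0
    nu_plane: float = 0.2          # in the radial-axial isotropy plane
    nu_circ_plane: float = 0.3     # major Poisson ratio, fiber -> plane
    G_circ_plane: float = 57.7     # out-of-plane shear modulus

    @property
    def G_plane(self) -> float:
        return self.E_plane / (2 * (1 + self.nu_plane))

    def validate(self) -> None:
        if min(self.E_circ, self.E_plane, self.G_circ_plane) <= 0:
            raise MaterialParameterError("moduli must be positive")
        if self.nu_circ_plane ** 2 >= self.E_circ / self.E_plane:
            raise MaterialParameterError(
                "thermodynamic restriction violated: nu_cp^2 < E_circ/E_plane")
        S = self.compliance_local()
        if np.linalg.eigvalsh(S).min() <= 0:
            raise MaterialParameterError(
                "compliance not positive definite (check Poisson ratios)")

    def compliance_local(self) -> np.ndarray:
        """Compliance in the (circ, radial, axial) frame."""
        S = np.zeros((6, 6))
        S[0, 0] = 1.0 / self.E_circ
        S[1, 1] = S[2, 2] = 1.0 / self.E_plane
        S[0, 1] = S[1, 0] = S[0, 2] = S[2, 0] = -self.nu_circ_plane / self.E_circ
        S[1, 2] = S[2, 1] = -self.nu_plane / self.E_plane
        S[3, 3] = 1.0 / self.G_plane          # shear in the isotropy plane (23)
        S[4, 4] = S[5, 5] = 1.0 / self.G_circ_plane   # (13), (12)
        return S

    def stiffness_local(self) -> np.ndarray:
        self.validate()
        return np.linalg.inv(self.compliance_local())


def _bond_strain_matrix(R: np.ndarray) -> np.ndarray:
    """Voigt transformation of engineering strain: eps_local = N eps_global,
    where local = R @ global (rows of R are the local axes)."""
    pairs = [(1, 2), (0, 2), (0, 1)]
    N = np.zeros((6, 6))
    for i in range(3):
        for j in range(3):
            N[i, j] = R[i, j] ** 2
        for col, (p, q) in enumerate(pairs):
            N[i, 3 + col] = R[i, p] * R[i, q]
    for row, (a, b) in enumerate(pairs):
        for j in range(3):
            N[3 + row, j] = 2 * R[a, j] * R[b, j]
        for col, (p, q) in enumerate(pairs):
            N[3 + row, 3 + col] = R[a, p] * R[b, q] + R[a, q] * R[b, p]
    return N


def stiffness_trans_iso(mat: TransverselyIsotropicElastic,
                        frame: np.ndarray) -> np.ndarray:
    """Stiffness in global axes for a local orthonormal triad.

    ``frame`` rows are the (circumferential, radial, axial) unit vectors.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.allclose(frame @ frame.T, np.eye(3), atol=1e-8):
        raise MaterialParameterError("frame must be orthonormal")
    C_loc = mat.stiffness_local()
    N = _bond_strain_matrix(frame)
    # energy invariance: C_glob = N^T C_loc N
    return N.T @ C_loc @ N


def stiffness_trans_iso_batch(mat: TransverselyIsotropicElastic,
                              frames: np.ndarray) -> np.ndarray:
    """Vectorized version for per-element frames, shape (n, 3, 3)."""
    C_loc = mat.stiffness_local()
    out = np.empty((len(frames), 6, 6))
    for i, R in enumerate(frames):
        N = _bond_strain_matrix(R)
        out[i] = N.T @ C_loc @ N
    return out


# ---------------------------------------------------------------------------
# Fiber frames: circumferential / radial / axial per element
# ---------------------------------------------------------------------------

def compute_fiber_frames(centroids: np.ndarray, outer_margin_xy: np.ndarray,
                         region_centroid: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal triads (circ, radial, axial) at element centroids.

    The circumferential direction is the tangent of the level-set contour of
    the in-plane distance to the outer margin polygon; axial is global z;
    radial completes the right-handed triad (pointing outward).  Elements
    where the distance gradient degenerates (at the disc center) fall back to
    the azimuthal direction about the region centroid.
    """
    import shapely
    from shapely.geometry import LinearRing

    ring = LinearRing(outer_margin_xy)
    if region_centroid is None:
        region_centroid = centroids.mean(axis=0)
    delta = 0.1
    x, y = centroids[:, 0], centroids[:, 1]

    def dist(px, py):
        return shapely.distance(ring, shapely.points(np.column_stack([px, py])))

    gx = (dist(x + delta, y) - dist(x - delta, y)) / (2 * delta)
    gy = (dist(x, y + delta) - dist(x, y - delta)) / (2 * delta)
    gnorm = np.hypot(gx, gy)
    radial = np.column_stack([-gx, -gy, np.zeros_like(gx)])  # outward
    degenerate = gnorm < 1e-6
    if degenerate.any():   # at the disc center: azimuth about the centroid
        rx = x[degenerate] - region_centroid[0]
        ry = y[degenerate] - region_centroid[1]
        rn = np.hypot(rx, ry)
        rx = np.where(rn > 1e-9, rx / np.maximum(rn, 1e-30), 1.0)
        ry = np.where(rn > 1e-9, ry / np.maximum(rn, 1e-30), 0.0)
        radial[degenerate] = np.column_stack([rx, ry, np.zeros_like(rx)])
        gnorm = np.where(degenerate, 1.0, gnorm)
    radial[~degenerate] /= gnorm[~degenerate, None]

    axial = np.array([0.0, 0.0, 1.0])
    circ = np.cross(np.broadcast_to(axial, radial.shape), radial)
    circ /= np.linalg.norm(circ, axis=1, keepdims=True)
    radial = np.cross(np.broadcast_to(axial, circ.shape), circ)  # right-handed
    frames = np.empty((len(centroids), 3, 3))
    frames[:, 0] = circ
    frames[:, 1] = radial
    frames[:, 2] = np.broadcast_to(axial, circ.shape)
    return frames


# ---------------------------------------------------------------------------
# Neo-Hookean fibers (cruciates) and linear fibers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeoHookeanParams:
    C1: float                      # shear-like modulus, MPa
    D1: float                      # compressibility parameter, MPa^-1
    tension_only: bool = True

    def validate(self) -> None:
        if self.C1 <= 0 or self.D1 <= 0:
            raise MaterialParameterError("C1 and D1 must be positive")

    def energy_density(self, F: np.ndarray) -> float:
        """Compressible Neo-Hookean strain energy per unit reference volume:
        W = C1 (I1bar - 3) + (1/D1)(J - 1)^2 (material-point API)."""
        J = np.linalg.det(F)
        if J <= 0:
            raise ValueError("deformation gradient must preserve orientation")
        I1 = float(np.trace(F.T @ F))
        I1bar = I1 * J ** (-2.0 / 3.0)
        return self.C1 * (I1bar - 3.0) + (1.0 / self.D1) * (J - 1.0) ** 2

    def cauchy_uniaxial(self, stretch: float) -> float:
        """Incompressible uniaxial Cauchy stress sigma = 2 C1 (l^2 - 1/l)."""
        if stretch <= 0:
            raise ValueError("stretch must be positive")
        return 2.0 * self.C1 * (stretch ** 2 - 1.0 / stretch)


def neo_hookean_fiber_force(mat: NeoHookeanParams, stretch: float,
                            area: float) -> float:
    """Axial fiber force (N): Cauchy stress on the current cross-section
    area/stretch (incompressible), optionally zero in compression."""
    mat.validate()
    if stretch <= 0:
        raise ValueError("stretch must be positive")
    if mat.tension_only and stretch < 1.0:
        return 0.0
    sigma = mat.cauchy_uniaxial(stretch)
    return sigma * area / stretch


@dataclass(frozen=True)
class LinearFiber:
    E: float = 60.0
    tension_only: bool = True

    def force(self, stretch: float, area: float) -> float:
        if self.tension_only and stretch < 1.0:
            return 0.0
        return self.E * area * (stretch - 1.0)


# ---------------------------------------------------------------------------
# Default material cards
# ---------------------------------------------------------------------------

def default_material_cards() -> dict:
    """Region tag -> constitutive model, with the study's default parameters."""
    cartilage = IsotropicElastic(E=15.0, nu=0.3)
    meniscus = TransverselyIsotropicElastic()
    return {
        "femoral_cartilage_medial": cartilage,
        "femoral_cartilage_lateral": cartilage,
        "tibial_cartilage_medial": cartilage,
        "tibial_cartilage_lateral": cartilage,
        "meniscus_medial": meniscus,
        "meniscus_lateral": meniscus,
        "neo_hookean_acl": NeoHookeanParams(C1=5.08, D1=0.00683),
        "neo_hookean_pcl": NeoHookeanParams(C1=6.06, D1=0.0041),
        "ligament_linear": LinearFiber(E=60.0),
    }


def material_cards_to_dict(cards: dict) -> dict:
    out = {}
    for k, m in cards.items():
        d = {"type": type(m).__name__}
        d.update({f: getattr(m, f) for f in m.__dataclass_fields__})
        out[k] = d
    return out


def material_cards_from_dict(d: dict) -> dict:
    types = {c.__name__: c for c in (IsotropicElastic,
                                     TransverselyIsotropicElastic,
                                     NeoHookeanParams, LinearFiber)}
    out = {}
    for k, v in d.items():
        v = dict(v)
        cls = types[v.pop("type")]
        out[k] = cls(**v)
    return out
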