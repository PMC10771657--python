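"""Parametric synthetic tibiofemoral joint.

The package studies how the residual volume of a discoid lateral meniscus
(DLM) after partial meniscectomy changes tibiofemoral shear and compressive
stress.  No patient geometry ships with the package; instead an idealized
parametric joint emulates the anatomy the study needs:

* rigid femur and tibia (bone treated as rigid),
* two femoral condyles as convex bi-radius (sagittal/frontal) surfaces,
* shallow concave tibial plateau patches, each coated with a
  uniform-thickness articular-cartilage layer,
* a discoid lateral meniscus covering (nearly) the whole lateral plateau and
  a C-shaped medial meniscus,
* ligaments (ACL/PCL/MCL/LCL, patellar-quadriceps path) as fiber bundles.

Coordinate convention: x = medial->lateral, y = posterior->anterior,
z = inferior->superior; origin at the tibial plateau centroid; units mm.
The knee is posed in full extension (single static stance load case).

Construction is *conforming*: meniscus surfaces are offset a small clearance
(default 0.02 mm) from the facing cartilage, and the tibial dish shape is
derived from the condyle shape minus the meniscus thickness profile, so the
unloaded joint has a near-uniform initial gap.  Contact concentration in the
anterior horn (where stance-phase contact peaks in extension) is produced by
an anterior-posterior cartilage-thickness taper: cartilage is thinner
anteriorly, so the anterior load column is stiffer and takes more pressure.
The meniscus thickness profile itself is symmetric in y, which keeps the
equal-volume anterior/posterior split on the symmetry plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import meshing
from .meshing import Grid2D, TetBlock

REGION_TAGS = (
    "femoral_cartilage_medial", "femoral_cartilage_lateral",
    "tibial_cartilage_medial", "tibial_cartilage_lateral",
    "meniscus_medial", "meniscus_lateral",
)

LIGAMENT_NAMES = ("ACL", "PCL", "MCL", "LCL", "PAT")


class ConfigurationError(ValueError):
    """Invalid geometry configuration; message names the offending field."""


class GeometryConstructionError(RuntimeError):
    pass


def _default_attachments() -> dict:
    # (femur point, tibia point) in the lateral=+x convention, mm
    return {
        "ACL": ((8.0, -6.0, 12.0), (-2.0, 6.0, 0.0)),
        "PCL": ((-6.0, 4.0, 10.0), (2.0, -8.0, -3.0)),
        "MCL": ((-30.0, 0.0, 8.0), (-32.0, 0.0, -25.0)),
        "LCL": ((30.0, -2.0, 8.0), (32.0, -2.0, -25.0)),
        "PAT": ((0.0, 24.0, 30.0), (0.0, 26.0, -20.0)),
    }


@dataclass
class GeometryConfig:
    """Parameters of the synthetic joint.  All lengths in mm."""

    condyle_radius_sagittal: float = 35.0
    condyle_radius_frontal: float = 22.0
    condyle_spacing: float = 34.0            # distance between compartment centers
    plateau_halfwidths: tuple[float, float] = (15.0, 17.5)   # (ML, AP) semi-axes
    cartilage_thickness: float = 2.0
    meniscus_peripheral_height: float = 4.0
    meniscus_inner_height: float = 2.0
    discoid_coverage: float = 1.0            # fraction of lateral plateau covered
    medial_meniscus_inner_rim_ratio: float = 0.5
    ap_cartilage_taper: float = 0.25         # cartilage thinning fraction at y = +b
    contact_clearance: float = 0.02          # initial gap to cartilage, mm
    ligament_attachment_points: dict = field(default_factory=_default_attachments)
    ligament_fiber_counts: dict = field(
        default_factory=lambda: {n: 3 for n in LIGAMENT_NAMES})
    ligament_areas: dict = field(
        default_factory=lambda: {n: 40.0 for n in LIGAMENT_NAMES})  # mm^2 total
    random_seed: int = 0
    lateral_sign: int = 1                    # +1: lateral side at x > 0

    def validate(self) -> None:
        for name in ("condyle_radius_sagittal", "condyle_radius_frontal",
                     "condyle_spacing", "cartilage_thickness",
                     "meniscus_peripheral_height", "meniscus_inner_height",
                     "contact_clearance"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if any(v <= 0 for v in self.plateau_halfwidths):
            raise ConfigurationError("plateau_halfwidths must be strictly positive")
        if not (0.9 < self.discoid_coverage <= 1.0):
            raise ConfigurationError("discoid_coverage must lie in (0.9, 1.0]")
        if not (0.0 <= self.medial_meniscus_inner_rim_ratio < 0.95):
            raise ConfigurationError(
                "medial_meniscus_inner_rim_ratio must lie in [0, 0.95)")
        if self.cartilage_thickness >= self.condyle_radius_frontal:
            raise ConfigurationError(
                "cartilage_thickness must be smaller than condyle_radius_frontal")
        if not (0.0 <= self.ap_cartilage_taper < 0.9):
            raise ConfigurationError("ap_cartilage_taper must lie in [0, 0.9)")
        if self.meniscus_inner_height > self.meniscus_peripheral_height:
            raise ConfigurationError(
                "meniscus_inner_height must not exceed meniscus_peripheral_height")
        if self.lateral_sign not in (1, -1):
            raise ConfigurationError("lateral_sign must be +1 or -1")
        for lig in self.ligament_fiber_counts.values():
            if lig < 0:
                raise ConfigurationError("ligament_fiber_counts must be >= 0")

    def mirrored(self) -> "GeometryConfig":
        """Configuration of the joint reflected in the medial-lateral axis."""
        pts = {name: (tuple(np.array(f) * [-1, 1, 1]),
                      tuple(np.array(t) * [-1, 1, 1]))
               for name, (f, t) in self.ligament_attachment_points.items()}
        return replace(self, lateral_sign=-self.lateral_sign,
                       ligament_attachment_points=pts)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["plateau_halfwidths"] = list(self.plateau_halfwidths)
        d["ligament_attachment_points"] = {
            k: [list(f), list(t)]
            for k, (f, t) in self.ligament_attachment_points.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryConfig":
        d = dict(d)
        if "plateau_halfwidths" in d:
            d["plateau_halfwidths"] = tuple(d["plateau_halfwidths"])
        if "ligament_attachment_points" in d:
            d["ligament_attachment_points"] = {
                k: (tuple(v[0]), tuple(v[1]))
                for k, v in d["ligament_attachment_points"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Mesh containers
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    vertices: np.ndarray
    triangles: np.ndarray
    label: str = ""
    closed: bool = False

    def as_trimesh(self):
        import trimesh
        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles,
                               process=False)


@dataclass
class SolidRegion:
    boundary: SurfaceMesh
    tag: str
    parametric: "MeniscusParam | LayerParam | None" = None
    block: "TetBlock | None" = None      # explicit discretization, if the solid
                                         # was shaped by mesh-level operations

    @property
    def volume(self) -> float:
        return meshing.surface_volume(self.boundary.vertices,
                                      self.boundary.triangles)


@dataclass
class LigamentElement:
    name: str
    femur_points: np.ndarray     # (nf, 3) fiber endpoints on the femur
    tibia_points: np.ndarray     # (nf, 3) fiber endpoints on the tibia/patellar path
    cross_section_area: float    # mm^2 per fiber
    material_ref: str            # key into the material card table

    @property
    def rest_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.femur_points - self.tibia_points, axis=1)


# ---------------------------------------------------------------------------
# Compartment: all analytic surfaces of one tibiofemoral compartment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    side: str                    # 'medial' | 'lateral'
    xc: float
    yc: float
    a: float                     # ML semi-axis
    b: float                     # AP semi-axis
    r_frontal: float
    r_sagittal: float
    t_cartilage: float
    clearance: float
    h_inner: float
    h_peripheral: float
    taper: float

    @property
    def z_apex(self) -> float:
        # condyle (femoral-cartilage bottom) height above the dish center;
        # fixed so that the tibial bone dish passes through z = 0 at center
        return 2.0 * self.clearance + self.t_cartilage + self.h_inner

    def rho(self, x, y):
        return np.sqrt(((x - self.xc) / self.a) ** 2 +
                       ((y - self.yc) / self.b) ** 2)

    def condyle_z(self, x, y):
        """Femoral-cartilage bottom (articular) surface."""
        return (self.z_apex + (x - self.xc) ** 2 / (2 * self.r_frontal)
                + (y - self.yc) ** 2 / (2 * self.r_sagittal))

    def thickness(self, x, y):
        """Meniscus thickness profile: radial wedge, symmetric in y."""
        return self.h_inner + (self.h_peripheral - self.h_inner) * self.rho(x, y)

    def cartilage_thickness_at(self, y):
        """Cartilage thins anteriorly (stiffer anterior load column)."""
        return self.t_cartilage * (1.0 - self.taper * (y - self.yc) / self.b)

    def meniscus_top_z(self, x, y):
        return self.condyle_z(x, y) - self.clearance

    def meniscus_bottom_z(self, x, y):
        return self.meniscus_top_z(x, y) - self.thickness(x, y)

    def tibial_cartilage_top_z(self, x, y):
        return self.meniscus_bottom_z(x, y) - self.clearance

    def tibia_dish_z(self, x, y):
        return self.tibial_cartilage_top_z(x, y) - self.cartilage_thickness_at(y)

    def femoral_cartilage_top_z(self, x, y):
        return self.condyle_z(x, y) + self.cartilage_thickness_at(y)


# Parametric solid descriptions carried by SolidRegion so later stages can
# remesh at any resolution.

@dataclass(frozen=True)
class MeniscusParam:
    compartment: Compartment
    rho_inner: object            # float or callable theta -> rho

    def rho_inner_at(self, theta: np.ndarray) -> np.ndarray:
        if callable(self.rho_inner):
            return np.asarray(self.rho_inner(np.asarray(theta, dtype=float)))
        return np.full_like(np.asarray(theta, dtype=float), float(self.rho_inner))


@dataclass(frozen=True)
class LayerParam:
    compartment: Compartment
    kind: str                    # 'femoral_cartilage' | 'tibial_cartilage'


# ---------------------------------------------------------------------------
# Structured meshing of the parametric solids
# ---------------------------------------------------------------------------

@dataclass
class MeshSizes:
    """Target discretization.  ``in_plane`` is the nominal element edge (mm).

    The default (~1.5 mm in plane, two elements through each layer) is the
    study's coarsened working resolution; the reference 1.0 mm element size
    is one parameter away."""
    in_plane: float = 1.5
    nz_cartilage: int = 2
    nz_meniscus: int = 2

    def ntheta(self, comp: Compartment) -> int:
        n = int(math.ceil(2 * math.pi * max(comp.a, comp.b) / self.in_plane))
        return max(16, int(math.ceil(n / 4.0)) * 4)


def _radial_levels(comp: Compartment, rho_lo: float, rho_hi: float,
                   target: float, boundaries: tuple[float, ...] = ()) -> np.ndarray:
    """Radial grid on [rho_lo, rho_hi] honouring fixed ring boundaries."""
    bnds = sorted({rho_lo, rho_hi, *[b for b in boundaries
                                     if rho_lo < b < rho_hi]})
    levels = [rho_lo]
    scale = max(comp.a, comp.b)
    for lo, hi in zip(bnds[:-1], bnds[1:]):
        n = max(1, int(math.ceil((hi - lo) * scale / target)))
        levels.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(levels)


def mesh_meniscus(param: MeniscusParam, sizes: MeshSizes,
                  ring_boundaries: tuple[float, ...] = ()) -> TetBlock:
    """Tet-mesh a meniscus (possibly resected: per-angle inner boundary).

    With a constant inner boundary and explicit ``ring_boundaries`` the radial
    grid lines coincide with the partition rings, so ring volumes are exact
    sums of element volumes.  With a varying inner boundary (resected /
    blended models) each angular column is mapped affinely onto
    [rho_inner(theta), 1].
    """
    comp = param.compartment
    ntheta = sizes.ntheta(comp)
    theta = np.linspace(0.0, 2 * np.pi, ntheta, endpoint=False)
    rin = param.rho_inner_at(theta)
    rin_min = float(rin.min())
    base = _radial_levels(comp, rin_min, 1.0, sizes.in_plane, ring_boundaries)
    if np.allclose(rin, rin_min):
        rho_cols = np.broadcast_to(base, (ntheta, len(base))).copy()
    else:
        # map the base grid of [rin_min, 1] onto [rho_inner(theta), 1]
        t = (base - rin_min) / (1.0 - rin_min)
        rho_cols = rin[:, None] + t[None, :] * (1.0 - rin[:, None])
    grid = meshing.polar_grid((comp.xc, comp.yc), comp.a, comp.b, theta, rho_cols)
    x, y = grid.points[:, 0], grid.points[:, 1]
    return meshing.extrude(grid, comp.meniscus_bottom_z(x, y),
                           comp.meniscus_top_z(x, y), sizes.nz_meniscus)


def mesh_cartilage(param: LayerParam, sizes: MeshSizes) -> TetBlock:
    comp = param.compartment
    ntheta = sizes.ntheta(comp)
    theta = np.linspace(0.0, 2 * np.pi, ntheta, endpoint=False)
    levels = _radial_levels(comp, 0.0, 1.0, sizes.in_plane)
    rho_cols = np.broadcast_to(levels, (ntheta, len(levels))).copy()
    grid = meshing.polar_grid((comp.xc, comp.yc), comp.a, comp.b, theta, rho_cols)
    x, y = grid.points[:, 0], grid.points[:, 1]
    if param.kind == "femoral_cartilage":
        zb = comp.condyle_z(x, y)
        zt = comp.femoral_cartilage_top_z(x, y)
    elif param.kind == "tibial_cartilage":
        zb = comp.tibia_dish_z(x, y)
        zt = comp.tibial_cartilage_top_z(x, y)
    else:
        raise ValueError(param.kind)
    return meshing.extrude(grid, zb, zt, sizes.nz_cartilage)


def solid_from_block(block: TetBlock, tag: str,
                     parametric=None, keep_block: bool = False) -> SolidRegion:
    tris = meshing.boundary_surface(block.nodes, block.tets)
    surf = SurfaceMesh(vertices=block.nodes.copy(), triangles=tris,
                       label=tag, closed=True)
    return SolidRegion(boundary=surf, tag=tag, parametric=parametric,
                       block=block if keep_block else None)


# ---------------------------------------------------------------------------
# Knee assembly
# ---------------------------------------------------------------------------

@dataclass
class KneeGeometry:
    config: GeometryConfig
    compartments: dict            # 'medial'/'lateral' -> Compartment
    femur_surface: SurfaceMesh
    tibia_surface: SurfaceMesh
    solids: list                  # SolidRegion
    ligaments: list               # LigamentElement
    axes: dict

    def solid(self, tag: str) -> SolidRegion:
        for s in self.solids:
            if s.tag == tag:
                return s
        raise KeyError(tag)

    def replace_solid(self, tag: str, new: SolidRegion) -> "KneeGeometry":
        solids = [new if s.tag == tag else s for s in self.solids]
        return replace(self, solids=solids)


def _make_compartment(config: GeometryConfig, side: str) -> Compartment:
    s = config.lateral_sign
    xc = (s if side == "lateral" else -s) * config.condyle_spacing / 2.0
    a, b = config.plateau_halfwidths
    return Compartment(
        side=side, xc=xc, yc=0.0, a=a, b=b,
        r_frontal=config.condyle_radius_frontal,
        r_sagittal=config.condyle_radius_sagittal,
        t_cartilage=config.cartilage_thickness,
        clearance=config.contact_clearance,
        h_inner=config.meniscus_inner_height,
        h_peripheral=config.meniscus_peripheral_height,
        taper=config.ap_cartilage_taper,
    )


def build_discoid_meniscus(config: GeometryConfig,
                           sizes: MeshSizes | None = None) -> SolidRegion:
    """Watertight wedge-profiled disc covering the lateral plateau."""
    config.validate()
    sizes = sizes or MeshSizes()
    comp = _make_compartment(config, "lateral")
    rho_in = math.sqrt(max(0.0, 1.0 - config.discoid_coverage))
    param = MeniscusParam(compartment=comp, rho_inner=rho_in)
    block = mesh_meniscus(param, sizes)
    return solid_from_block(block, "meniscus_lateral", parametric=param)


def build_medial_meniscus(config: GeometryConfig,
                          sizes: MeshSizes | None = None) -> SolidRegion:
    """C-shaped counterpart: annulus with an inner rim opening."""
    config.validate()
    sizes = sizes or MeshSizes()
    comp = _make_compartment(config, "medial")
    param = MeniscusParam(compartment=comp,
                          rho_inner=config.medial_meniscus_inner_rim_ratio)
    block = mesh_meniscus(param, sizes)
    return solid_from_block(block, "meniscus_medial", parametric=param)


def _bone_patch(comp: Compartment, surface: str, ntheta: int = 32,
                nr: int = 6) -> tuple[np.ndarray, np.ndarray]:
    theta = np.linspace(0.0, 2 * np.pi, ntheta, endpoint=False)
    levels = np.linspace(0.0, 1.0, nr + 1)
    rho_cols = np.broadcast_to(levels, (ntheta, len(levels))).copy()
    grid = meshing.polar_grid((comp.xc, comp.yc), comp.a, comp.b, theta, rho_cols)
    x, y = grid.points[:, 0], grid.points[:, 1]
    if surface == "femur":
        z = comp.femoral_cartilage_top_z(x, y)
    else:
        z = comp.tibia_dish_z(x, y)
    verts = np.column_stack([x, y, z])
    return verts, grid.triangles


def _attachment_patch(point: np.ndarray, size: float = 1.0):
    """Small quad patch centered on a ligament attachment point."""
    p = np.asarray(point, dtype=float)
    verts = p + np.array([[-size, -size, 0], [size, -size, 0],
                          [size, size, 0], [-size, size, 0]])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    return verts, tris


def _merge_surfaces(parts, label: str) -> SurfaceMesh:
    verts, tris, off = [], [], 0
    for v, t in parts:
        verts.append(v)
        tris.append(t + off)
        off += len(v)
    return SurfaceMesh(vertices=np.vstack(verts), triangles=np.vstack(tris),
                       label=label, closed=False)


def build_knee_geometry(config: GeometryConfig,
                        sizes: MeshSizes | None = None) -> KneeGeometry:
    """Assemble the full synthetic joint in full extension."""
    config.validate()
    sizes = sizes or MeshSizes()
    comps = {side: _make_compartment(config, side)
             for side in ("medial", "lateral")}

    solids: list[SolidRegion] = []
    for side in ("medial", "lateral"):
        comp = comps[side]
        for kind, tag in (("femoral_cartilage", f"femoral_cartilage_{side}"),
                          ("tibial_cartilage", f"tibial_cartilage_{side}")):
            param = LayerParam(compartment=comp, kind=kind)
            solids.append(solid_from_block(mesh_cartilage(param, sizes), tag,
                                           parametric=param))
    solids.append(build_medial_meniscus(config, sizes))
    solids.append(build_discoid_meniscus(config, sizes))

    ligaments = _build_ligaments(config)

    femur_parts = [_bone_patch(comps[s], "femur") for s in ("medial", "lateral")]
    tibia_parts = [_bone_patch(comps[s], "tibia") for s in ("medial", "lateral")]
    for lig in ligaments:
        for p in lig.femur_points:
            femur_parts.append(_attachment_patch(p))
        for p in lig.tibia_points:
            tibia_parts.append(_attachment_patch(p))
    femur_surface = _merge_surfaces(femur_parts, "femur")
    tibia_surface = _merge_surfaces(tibia_parts, "tibia_fibula")

    geom = KneeGeometry(
        config=config, compartments=comps,
        femur_surface=femur_surface, tibia_surface=tibia_surface,
        solids=solids, ligaments=ligaments,
        axes={"x": "medial->lateral" if config.lateral_sign == 1
              else "lateral->medial",
              "y": "posterior->anterior", "z": "inferior->superior",
              "origin": "tibial plateau centroid", "units": "mm, MPa, N"},
    )
    _check_no_interpenetration(geom)
    return geom


def _build_ligaments(config: GeometryConfig) -> list[LigamentElement]:
    ligaments = []
    for name in LIGAMENT_NAMES:
        n = int(config.ligament_fiber_counts.get(name, 0))
        if n == 0:
            continue
        fem, tib = (np.asarray(p, dtype=float)
                    for p in config.ligament_attachment_points[name])
        # spread fibers deterministically along y around the attachment line
        offsets = np.linspace(-1.0, 1.0, n)[:, None] * np.array([0.0, 1.0, 0.0])
        mat = "neo_hookean_acl" if name == "ACL" else (
            "neo_hookean_pcl" if name == "PCL" else "ligament_linear")
        ligaments.append(LigamentElement(
            name=name,
            femur_points=fem + offsets,
            tibia_points=tib + offsets,
            cross_section_area=config.ligament_areas[name] / n,
            material_ref=mat,
        ))
    return ligaments


def _check_no_interpenetration(geom: KneeGeometry, tol: float = 0.01) -> None:
    """The conforming construction guarantees clearance-sized gaps; verify on
    sampled points that facing surfaces do not overlap beyond ``tol`` mm."""
    for k, side in enumerate(("medial", "lateral")):
        comp = geom.compartments[side]
        rng = np.random.default_rng(geom.config.random_seed + k)
        rho = np.sqrt(rng.uniform(0, 1, 200))
        th = rng.uniform(0, 2 * np.pi, 200)
        x = comp.xc + comp.a * rho * np.cos(th)
        y = comp.yc + comp.b * rho * np.sin(th)
        gap_top = comp.condyle_z(x, y) - comp.meniscus_top_z(x, y)
        gap_bot = comp.meniscus_bottom_z(x, y) - comp.tibial_cartilage_top_z(x, y)
        if gap_top.min() < -tol or gap_bot.min() < -tol:
            raise GeometryConstructionError(
                f"solids interpenetrate in the {side} compartment")
        if np.any(comp.thickness(x, y) <= 0):
            raise GeometryConstructionError(
                f"non-positive meniscus thickness in the {side} compartment")
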