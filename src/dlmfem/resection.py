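"""Virtual partial meniscectomy by volume ratio.

The discoid meniscus is divided into five concentric zones — 15/15/15/15%
from the inner free margin outward plus a 40% peripheral rim — and by an
equal-volume plane perpendicular to the anterior-posterior axis, giving ten
regions.  Saucerization models remove whole inner zones independently on the
anterior and posterior side; residual fractions per side come from
{100, 85, 70, 55, 40}% with at most a 30-point anterior/posterior difference,
yielding the 15-model family (intact "100a100p" through "40a40p").  The
peripheral 40% rim is never removed (conventional meniscectomy preserves a
peripheral rim).  Models with unequal sides get their junction step blended
over a finite band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import meshing
from .geometry import MeniscusParam, MeshSizes, SolidRegion, mesh_meniscus, solid_from_block

_LEVELS = (1.00, 0.85, 0.70, 0.55, 0.40)


class PartitionError(RuntimeError):
    pass


class ResectionSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PartitionScheme:
    ring_fractions: tuple = (0.15, 0.15, 0.15, 0.15, 0.40)  # innermost -> rim
    ap_split_rule: str = "equal_volume"

    def validate(self) -> None:
        if abs(sum(self.ring_fractions) - 1.0) > 1e-12:
            raise ValueError("ring_fractions must sum to 1.0")
        if any(f <= 0 for f in self.ring_fractions):
            raise ValueError("ring_fractions must be positive")


@dataclass
class MeniscusPartition:
    source: SolidRegion
    scheme: PartitionScheme
    sizes: MeshSizes
    ring_rhos: np.ndarray          # ring boundaries [rho_in, r1..r_{k-1}, 1]
    total_volume: float
    ring_volumes: np.ndarray       # realized, innermost first
    split_y: float | None = None
    region_volumes: dict = field(default_factory=dict)  # (ring, side) -> mm^3
    anterior_volume: float | None = None       # exact clipped side volumes
    posterior_volume: float | None = None
    _side_cut_cache: dict = field(default_factory=dict, repr=False)

    @property
    def realized_fractions(self) -> np.ndarray:
        return self.ring_volumes / self.total_volume


@dataclass(frozen=True)
class ResectionSpec:
    anterior_fraction: float
    posterior_fraction: float

    def validate(self) -> None:
        for name in ("anterior_fraction", "posterior_fraction"):
            v = getattr(self, name)
            if not any(abs(v - l) < 1e-9 for l in _LEVELS):
                raise ResectionSpecError(
                    f"{name}={v} not reachable by whole-ring removal "
                    f"(allowed: {_LEVELS})")
        a, p = self.anterior_fraction, self.posterior_fraction
        if abs(a - p) > 0.30 + 1e-9:
            raise ResectionSpecError(
                "anterior/posterior difference exceeds 30 points")
        if (abs(a - 1.0) < 1e-9) != (abs(p - 1.0) < 1e-9):
            raise ResectionSpecError("100% pairs only with 100%")


@dataclass
class ResectionModel:
    name: str
    spec: ResectionSpec
    solid: SolidRegion
    realized_residual_volume: float
    realized_residual_fraction: float
    smoothing_applied: bool = False
    partition: MeniscusPartition | None = None


# ---------------------------------------------------------------------------
# Volume helpers
# ---------------------------------------------------------------------------

def compute_volume(solid) -> float:
    """Signed enclosed volume (divergence theorem) of a watertight surface."""
    if isinstance(solid, SolidRegion):
        verts, tris = solid.boundary.vertices, solid.boundary.triangles
    else:
        verts, tris = solid
    edges = np.concatenate([np.sort(tris[:, [0, 1]], axis=1),
                            np.sort(tris[:, [1, 2]], axis=1),
                            np.sort(tris[:, [0, 2]], axis=1)])
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts != 2):
        raise ValueError("surface is not closed (open or non-manifold edges)")
    return meshing.surface_volume(verts, tris)


def _meniscus_block(param: MeniscusParam, sizes: MeshSizes,
                    boundaries=()) -> tuple:
    block = mesh_meniscus(param, sizes, ring_boundaries=tuple(boundaries))
    vols = meshing.tet_volumes(block.nodes, block.tets)
    return block, vols


def _ring_index(block, param: MeniscusParam, boundaries: np.ndarray) -> np.ndarray:
    """Ring id per tet (0 = innermost) from centroid elliptic radius."""
    comp = param.compartment
    cent = block.nodes[block.tets].mean(axis=1)
    rho = comp.rho(cent[:, 0], cent[:, 1])
    return np.clip(np.searchsorted(boundaries[1:-1], rho), 0,
                   len(boundaries) - 2)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def partition_rings(meniscus: SolidRegion, scheme: PartitionScheme,
                    sizes: MeshSizes | None = None,
                    tol_points: float = 0.5) -> MeniscusPartition:
    """Find concentric zone boundaries by bisection on the inward offset.

    Cumulative zone volumes (innermost first) match the scheme targets within
    ``tol_points`` percentage points; boundaries are realized as mesh grid
    lines so zone volumes are exact element sums.
    """
    scheme.validate()
    sizes = sizes or MeshSizes()
    param = meniscus.parametric
    if not isinstance(param, MeniscusParam):
        raise PartitionError("meniscus carries no parametric description")
    rho_in = float(np.min(param.rho_inner_at(np.linspace(0, 2 * np.pi, 8))))
    if callable(param.rho_inner):
        raise PartitionError("partitioning expects an intact (unresected) meniscus")

    targets = np.cumsum(scheme.ring_fractions)[:-1]   # cumulative from inner
    found: list[float] = []

    def realized_cumulative(rho_b: float, fixed: list[float]) -> float:
        bounds = [rho_in, *fixed, rho_b, 1.0]
        block, vols = _meniscus_block(param, sizes, boundaries=bounds)
        ridx = _ring_index(block, param, np.asarray(bounds))
        total = vols.sum()
        inner = vols[ridx < len(fixed) + 1].sum()
        return inner / total

    for t in targets:
        lo = found[-1] if found else rho_in
        # bracket check at the outer end
        if realized_cumulative(1.0 - 1e-6, found) < t:
            raise PartitionError(
                f"cannot reach cumulative fraction {t:.2f}; achievable range "
                f"ends below target (degenerate geometry)")
        a_, b_ = lo + 1e-6, 1.0 - 1e-6
        for _ in range(60):
            mid = 0.5 * (a_ + b_)
            if realized_cumulative(mid, found) < t:
                a_ = mid
            else:
                b_ = mid
            if b_ - a_ < 1e-9:
                break
        found.append(0.5 * (a_ + b_))

    bounds = np.array([rho_in, *found, 1.0])
    block, vols = _meniscus_block(param, sizes, boundaries=bounds)
    ridx = _ring_index(block, param, bounds)
    nring = len(scheme.ring_fractions)
    ring_volumes = np.array([vols[ridx == k].sum() for k in range(nring)])
    total = vols.sum()
    realized = ring_volumes / total
    err = np.abs(realized - np.asarray(scheme.ring_fractions)) * 100.0
    if np.any(err > tol_points):
        raise PartitionError(
            f"ring volume targets missed by up to {err.max():.2f} points")
    return MeniscusPartition(source=meniscus, scheme=scheme, sizes=sizes,
                             ring_rhos=bounds, total_volume=float(total),
                             ring_volumes=ring_volumes)


def split_anterior_posterior(partition: MeniscusPartition,
                             tol: float = 0.005) -> MeniscusPartition:
    """Position the equal-volume split plane (normal to the AP axis) by
    bisection on exact clipped tet volumes, then tag the 10 sub-regions."""
    param = partition.source.parametric
    block, vols = _meniscus_block(param, partition.sizes,
                                  boundaries=partition.ring_rhos)
    total = vols.sum()
    y_lo = block.nodes[:, 1].min()
    y_hi = block.nodes[:, 1].max()
    for _ in range(60):
        mid = 0.5 * (y_lo + y_hi)
        below = meshing.clipped_tet_volume_below(block.nodes, block.tets, 1, mid)
        if below < 0.5 * total:
            y_lo = mid
        else:
            y_hi = mid
        if y_hi - y_lo < 1e-7:
            break
    split_y = 0.5 * (y_lo + y_hi)

    ridx = _ring_index(block, param, partition.ring_rhos)
    cent = block.nodes[block.tets].mean(axis=1)
    side = np.where(cent[:, 1] > split_y, "anterior", "posterior")
    region_volumes = {}
    for k in range(len(partition.scheme.ring_fractions)):
        for s in ("anterior", "posterior"):
            region_volumes[(k, s)] = float(
                vols[(ridx == k) & (side == s)].sum())
    va = sum(v for (k, s), v in region_volumes.items() if s == "anterior")
    vp = total - va
    if abs(va - vp) / total > tol:
        raise PartitionError(
            f"anterior/posterior volumes unequal beyond tolerance "
            f"({va:.2f} vs {vp:.2f} mm^3)")
    v_post_exact = meshing.clipped_tet_volume_below(block.nodes, block.tets,
                                                    1, split_y)
    return replace(partition, split_y=float(split_y),
                   region_volumes=region_volumes,
                   anterior_volume=float(total - v_post_exact),
                   posterior_volume=float(v_post_exact))


def _rings_removed(fraction: float) -> int:
    return int(round((1.0 - fraction) / 0.15))


def model_name(spec: ResectionSpec) -> str:
    return (f"{int(round(spec.anterior_fraction * 100))}a"
            f"{int(round(spec.posterior_fraction * 100))}p")


def enumerate_family() -> list[ResectionSpec]:
    """The intact model plus every admissible anterior/posterior pair."""
    specs = [ResectionSpec(1.00, 1.00)]
    for a in _LEVELS[1:]:
        for p in _LEVELS[1:]:
            if abs(a - p) <= 0.30 + 1e-9:
                specs.append(ResectionSpec(a, p))
    for s in specs:
        s.validate()
    return specs


def _cut_margin(rho_a: float, rho_p: float, comp, split_y: float,
                band: float = 0.0, center_shift: float = 0.0):
    """Inner-margin radius as a function of angle for a two-sided cut.

    Anterior of the split plane the margin sits at ``rho_a``, posterior at
    ``rho_p``; where the plane crosses between the two radii the cut wall
    follows the plane itself (margin = plane-crossing radius).  ``band`` > 0
    additionally blends the margin over that arc length of rim around each
    junction (the post-resection smoothing)."""
    if abs(rho_a - rho_p) < 1e-15 and band == 0.0:
        return float(rho_a)
    y_rel = split_y - comp.yc
    rho_bar = max(0.5 * (rho_a + rho_p), 1e-6)

    def margin0(theta):
        theta = np.asarray(theta, dtype=float)
        s = np.sin(theta)
        y_at_a = comp.b * rho_a * s
        y_at_p = comp.b * rho_p * s
        # tolerance keeps columns lying on the split plane in the crossing
        # branch (they take the mid radius, preserving mirror symmetry)
        eps = 1e-6 * comp.b
        out = np.where((y_at_a > y_rel + eps) & (y_at_p > y_rel + eps), rho_a,
                       np.where((y_at_a < y_rel - eps) & (y_at_p < y_rel - eps),
                                rho_p, 0.0))
        crossing = out == 0.0
        if np.any(crossing):
            with np.errstate(divide="ignore", invalid="ignore"):
                rho_star = np.where(np.abs(s) > 1e-12, y_rel / (comp.b * s),
                                    rho_bar)
            lo, hi = min(rho_a, rho_p), max(rho_a, rho_p)
            out = np.where(crossing, np.clip(rho_star, lo, hi), out)
        return out

    if band <= 0 or abs(rho_a - rho_p) < 1e-15:
        return margin0

    # junction angles: where the mid-radius margin point crosses the plane
    arg = np.clip(y_rel / (comp.b * rho_bar), -1.0, 1.0)
    th_c = math.asin(arg)
    centers = (th_c, math.pi - th_c)

    def margin(theta):
        theta = np.asarray(theta, dtype=float)
        out = margin0(theta)
        # orientation: anterior lies at increasing theta near the first
        # junction and decreasing theta near the second
        for c, orient in zip(centers, (1.0, -1.0)):
            r_loc = math.hypot(comp.a * rho_bar * math.cos(c),
                               comp.b * rho_bar * math.sin(c))
            c_eff = c + orient * center_shift / r_loc
            half = band / (2.0 * r_loc)          # half-band in angle
            s = (theta - c_eff + np.pi) % (2 * np.pi) - np.pi
            mask = np.abs(s) <= half
            if np.any(mask):
                lo_val = margin0(np.array([c_eff - half]))[0]
                hi_val = margin0(np.array([c_eff + half]))[0]
                u = np.clip(s / (2 * half) + 0.5, 0.0, 1.0)
                w = u * u * (3 - 2 * u)      # C1 smoothstep
                out = np.where(mask, lo_val + (hi_val - lo_val) * w, out)
        return out

    return margin


def _side_cut_radius(partition: MeniscusPartition, side: str,
                     fraction: float, sizes: MeshSizes) -> float:
    """Cut radius leaving exactly ``fraction`` of the side's volume.

    Starts from the nominal global ring boundary and refines by bisection on
    the side-resolved residual volume (clipped at the split plane); cached
    per (side, fraction) since the solution is independent of the other
    side's cut."""
    key = (side, round(fraction, 6), sizes.in_plane)
    if key in partition._side_cut_cache:
        return partition._side_cut_cache[key]
    param = partition.source.parametric
    comp = param.compartment
    rho_in = float(partition.ring_rhos[0])
    if abs(fraction - 1.0) < 1e-12:
        partition._side_cut_cache[key] = rho_in
        return rho_in
    v_side = (partition.anterior_volume if side == "anterior"
              else partition.posterior_volume)
    target = fraction * v_side
    y0 = partition.split_y

    def residual_side(rho: float) -> float:
        p = MeniscusParam(compartment=comp, rho_inner=float(rho))
        boundaries = tuple(b for b in partition.ring_rhos[1:-1] if b > rho)
        block = mesh_meniscus(p, sizes, ring_boundaries=boundaries)
        v_post = meshing.clipped_tet_volume_below(block.nodes, block.tets,
                                                  1, y0)
        total = meshing.tet_volumes(block.nodes, block.tets).sum()
        return v_post if side == "posterior" else total - v_post

    lo, hi = rho_in, 0.995
    if residual_side(hi) > target:
        raise PartitionError(
            f"{side} fraction {fraction} unreachable: residual at the rim "
            f"exceeds the target")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if residual_side(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    rho = 0.5 * (lo + hi)
    partition._side_cut_cache[key] = rho
    return rho


def resect(partition: MeniscusPartition, spec: ResectionSpec,
           sizes: MeshSizes | None = None) -> ResectionModel:
    """Remove inner zones innermost-first, independently per side."""
    spec.validate()
    if partition.split_y is None:
        partition = split_anterior_posterior(partition)
    sizes = sizes or partition.sizes
    param = partition.source.parametric
    comp = param.compartment
    ka = _rings_removed(spec.anterior_fraction)
    kp = _rings_removed(spec.posterior_fraction)
    nring = len(partition.ring_rhos) - 1
    if max(ka, kp) >= nring:
        raise ResectionSpecError("peripheral rim cannot be removed")
    rho_a = _side_cut_radius(partition, "anterior", spec.anterior_fraction,
                             sizes)
    rho_p = _side_cut_radius(partition, "posterior", spec.posterior_fraction,
                             sizes)
    inner = _cut_margin(rho_a, rho_p, comp, partition.split_y)
    new_param = MeniscusParam(compartment=comp, rho_inner=inner)

    remaining = tuple(b for b in partition.ring_rhos[1:-1]
                      if b > max(rho_a, rho_p))
    block = mesh_meniscus(new_param, sizes, ring_boundaries=remaining)
    solid = solid_from_block(block, partition.source.tag, parametric=new_param,
                             keep_block=True)
    vol = float(meshing.tet_volumes(block.nodes, block.tets).sum())
    model = ResectionModel(
        name=model_name(spec), spec=spec, solid=solid,
        realized_residual_volume=vol,
        realized_residual_fraction=vol / partition.total_volume,
        smoothing_applied=False, partition=partition)
    target = 0.5 * (spec.anterior_fraction + spec.posterior_fraction)
    if abs(model.realized_residual_fraction - target) > 0.01:
        raise PartitionError(
            f"residual fraction {model.realized_residual_fraction:.4f} "
            f"misses target {target:.4f} beyond 1%")
    return model


def smooth_junction(model: ResectionModel, band_width: float = 3.0,
                    sizes: MeshSizes | None = None,
                    max_volume_drift: float = 0.01) -> ResectionModel:
    """Blend the anterior/posterior step over a band of given width.

    The inner-margin radius jump at the split plane is replaced by a
    smoothstep transition over ``band_width`` mm of rim arc length; the mesh
    is regenerated from the blended boundary.  Equal-fraction models (no
    step) and a zero band width return the model unchanged.
    """
    spec = model.spec
    if band_width <= 0 or abs(spec.anterior_fraction
                              - spec.posterior_fraction) < 1e-12:
        return model
    partition = model.partition
    sizes = sizes or partition.sizes
    comp = partition.source.parametric.compartment
    rho_a = _side_cut_radius(partition, "anterior", spec.anterior_fraction,
                             sizes)
    rho_p = _side_cut_radius(partition, "posterior", spec.posterior_fraction,
                             sizes)
    remaining = tuple(b for b in partition.ring_rhos[1:-1]
                      if b > max(rho_a, rho_p))

    def build(shift: float):
        inner = _cut_margin(rho_a, rho_p, comp, partition.split_y,
                            band=band_width, center_shift=shift)
        p = MeniscusParam(compartment=comp, rho_inner=inner)
        blk = mesh_meniscus(p, sizes, ring_boundaries=remaining)
        return p, blk, float(meshing.tet_volumes(blk.nodes, blk.tets).sum())

    # the smoothstep blend is not exactly volume-neutral; sliding the blend
    # centers along the rim arc restores the resected volume
    target = model.realized_residual_volume
    new_param, block, vol = build(0.0)
    if abs(vol - target) / target > 2e-4:
        lo_s, hi_s = -1.2, 1.2
        v_lo, v_hi = build(lo_s)[2], build(hi_s)[2]
        if min(v_lo, v_hi) <= target <= max(v_lo, v_hi):
            increasing = v_hi > v_lo
            for _ in range(25):
                mid = 0.5 * (lo_s + hi_s)
                new_param, block, vol = build(mid)
                if (vol < target) == increasing:
                    lo_s = mid
                else:
                    hi_s = mid
                if abs(vol - target) / target < 2e-4:
                    break
        elif abs(v_lo - target) < abs(vol - target) or \
                abs(v_hi - target) < abs(vol - target):
            shift = lo_s if abs(v_lo - target) < abs(v_hi - target) else hi_s
            new_param, block, vol = build(shift)
    drift = abs(vol - target) / target
    if drift > max_volume_drift:
        raise PartitionError(
            f"smoothing changed the volume by {100 * drift:.2f}% "
            f"(> {100 * max_volume_drift:.0f}%); original model retained")
    solid = solid_from_block(block, partition.source.tag, parametric=new_param,
                             keep_block=True)
    return replace(model, solid=solid, realized_residual_volume=vol,
                   realized_residual_fraction=vol / partition.total_volume,
                   smoothing_applied=True)


def build_family(partition: MeniscusPartition, band_width: float = 3.0,
                 sizes: MeshSizes | None = None) -> list[ResectionModel]:
    """All 15 models, smoothed where anterior/posterior fractions differ."""
    models = []
    for spec in enumerate_family():
        m = resect(partition, spec, sizes=sizes)
        if abs(spec.anterior_fraction - spec.posterior_fraction) > 1e-12:
            m = smooth_junction(m, band_width=band_width, sizes=sizes)
        models.append(m)
    return models
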