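"""Partition, anterior/posterior split, resection family, smoothing."""

import dataclasses
import math

import numpy as np
import pytest
import trimesh

from dlmfem import (GeometryConfig, PartitionScheme, ResectionSpec,
                    build_discoid_meniscus, build_family, compute_volume,
                    enumerate_family, model_name, partition_rings, resect,
                    smooth_junction, split_anterior_posterior)
from dlmfem.geometry import Compartment, MeniscusParam, MeshSizes, mesh_meniscus, solid_from_block
from dlmfem.meshing import dihedral_angles
from dlmfem.resection import ResectionSpecError

FIG4_NAMES = {"100a100p", "85a85p", "85a70p", "85a55p", "70a85p", "70a70p",
              "70a55p", "70a40p", "55a85p", "55a70p", "55a55p", "55a40p",
              "40a70p", "40a55p", "40a40p"}


def flat_disc_solid(radius=10.0, height=2.0, ntheta=48):
    """Uniform-thickness circular disc (closed-form partition oracle)."""
    comp = Compartment(side="lateral", xc=0.0, yc=0.0, a=radius, b=radius,
                       r_frontal=1e9, r_sagittal=1e9, t_cartilage=1.0,
                       clearance=0.01, h_inner=height, h_peripheral=height,
                       taper=0.0)
    param = MeniscusParam(compartment=comp, rho_inner=0.0)
    sizes = MeshSizes(in_plane=1.0)
    block = mesh_meniscus(param, sizes)
    return solid_from_block(block, "meniscus_lateral", parametric=param), sizes


class TestPartition:
    def test_default_scheme_fractions_within_half_point(self, partition):
        realized = partition.realized_fractions * 100
        targets = np.asarray(partition.scheme.ring_fractions) * 100
        assert np.abs(realized - targets).max() <= 0.5

    def test_single_region_scheme_is_identity(self, discoid, coarse_sizes):
        part = partition_rings(discoid, PartitionScheme(ring_fractions=(1.0,)),
                               sizes=coarse_sizes)
        assert abs(part.realized_fractions[0] - 1.0) < 1e-9
        assert abs(part.total_volume - discoid.volume) / discoid.volume < 0.02

    def test_flat_disc_half_split_radius_closed_form(self):
        """On a uniform disc the 50% boundary sits at R*sqrt(0.5)."""
        solid, sizes = flat_disc_solid()
        part = partition_rings(solid, PartitionScheme(ring_fractions=(0.5, 0.5)),
                               sizes=sizes)
        assert abs(part.ring_rhos[1] - math.sqrt(0.5)) < 0.01 * math.sqrt(0.5)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            PartitionScheme(ring_fractions=(0.5, 0.4)).validate()


class TestSplit:
    def test_symmetric_meniscus_splits_on_symmetry_plane(self, partition):
        assert abs(partition.split_y - 0.0) < 0.1

    def test_anterior_posterior_volumes_conserve_total(self, partition):
        total = sum(partition.region_volumes.values())
        assert abs(total - partition.total_volume) / partition.total_volume < 0.005
        va = sum(v for (k, s), v in partition.region_volumes.items()
                 if s == "anterior")
        vp = partition.total_volume - va
        assert abs(va - vp) / partition.total_volume < 0.005

    def test_translated_meniscus_shifts_split_plane(self, default_config,
                                                    coarse_sizes):
        cfg = GeometryConfig()
        men = build_discoid_meniscus(cfg, sizes=coarse_sizes)
        part0 = split_anterior_posterior(
            partition_rings(men, PartitionScheme(), sizes=coarse_sizes))
        shifted = dataclasses.replace(
            men,
            parametric=MeniscusParam(
                compartment=dataclasses.replace(men.parametric.compartment,
                                                yc=men.parametric.compartment.yc + 5.0),
                rho_inner=men.parametric.rho_inner))
        part1 = split_anterior_posterior(
            partition_rings(shifted, PartitionScheme(), sizes=coarse_sizes))
        assert abs((part1.split_y - part0.split_y) - 5.0) < 0.1


class TestResect:
    def test_identity_spec_returns_source_volume(self, partition):
        m = resect(partition, ResectionSpec(1.0, 1.0))
        assert abs(m.realized_residual_fraction - 1.0) < 1e-9

    def test_equal_split_arithmetic(self, partition):
        m = resect(partition, ResectionSpec(0.85, 0.70))
        assert abs(m.realized_residual_fraction - 0.775) < 0.01

    def test_deepest_resection_keeps_positive_rim_width(self, partition):
        m = resect(partition, ResectionSpec(0.40, 0.40))
        comp = partition.source.parametric.compartment
        rho_cut = m.solid.parametric.rho_inner
        rho_cut = float(rho_cut) if not callable(rho_cut) else float(
            np.max(rho_cut(np.linspace(0, 2 * np.pi, 32))))
        width_mm = (1.0 - rho_cut) * min(comp.a, comp.b)
        assert width_mm > 0
        # report-style sanity: a few millimetres of rim remain
        assert 1.0 < width_mm < 10.0

    def test_unreachable_fractions_rejected(self, partition):
        with pytest.raises(ResectionSpecError):
            resect(partition, ResectionSpec(0.60, 0.60))
        with pytest.raises(ResectionSpecError):
            ResectionSpec(1.0, 0.85).validate()
        with pytest.raises(ResectionSpecError):
            ResectionSpec(0.85, 0.40).validate()

    def test_volume_conservation_residual_plus_removed(self, partition,
                                                       coarse_sizes):
        m = resect(partition, ResectionSpec(0.70, 0.70))
        removed_frac = 1.0 - m.realized_residual_fraction
        assert abs(removed_frac - 0.30) < 0.005

    def test_mirror_specs_have_equal_volume(self, partition):
        a = resect(partition, ResectionSpec(0.85, 0.55))
        b = resect(partition, ResectionSpec(0.55, 0.85))
        assert abs(a.realized_residual_volume - b.realized_residual_volume) \
            / a.realized_residual_volume < 0.005

    def test_monotone_nesting(self, partition):
        """The 55/55 residual is contained in the 70/70 residual."""
        from conftest import points_inside_surface
        inner = resect(partition, ResectionSpec(0.55, 0.55))
        outer = resect(partition, ResectionSpec(0.70, 0.70))
        blk = inner.solid.block
        cents = blk.nodes[blk.tets].mean(axis=1)
        rng = np.random.default_rng(7)
        pts = cents[rng.choice(len(cents), 200, replace=False)]
        inside = points_inside_surface(outer.solid.boundary.vertices,
                                       outer.solid.boundary.triangles, pts)
        assert inside.mean() >= 0.995


class TestSmoothing:
    def test_equal_fraction_model_unchanged(self, partition):
        m = resect(partition, ResectionSpec(0.70, 0.70))
        s = smooth_junction(m, band_width=3.0)
        assert s is m

    def test_zero_band_is_identity(self, partition):
        m = resect(partition, ResectionSpec(0.85, 0.55))
        s = smooth_junction(m, band_width=0.0)
        assert s is m

    def test_smoothing_reduces_step_and_conserves_volume(self, partition):
        m = resect(partition, ResectionSpec(0.85, 0.55))
        s = smooth_junction(m, band_width=3.0)
        assert s.smoothing_applied
        dv = abs(s.realized_residual_volume - m.realized_residual_volume)
        assert dv / m.realized_residual_volume <= 0.01
        tm = s.solid.boundary.as_trimesh()
        assert tm.is_watertight

        def junction_wall_dihedral(model):
            """Sharpest crease between wall facets near the junction (the
            free-margin top corner, present in every saucerized model, is
            excluded by the facet-orientation filter)."""
            v = model.solid.boundary.vertices
            t = model.solid.boundary.triangles
            comp = partition.source.parametric.compartment
            n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            cent = v[t].mean(axis=1)
            rho = comp.rho(cent[:, 0], cent[:, 1])
            sel = ((np.abs(n[:, 2]) < 0.8)
                   & (np.abs(cent[:, 1] - partition.split_y) < 4.0)
                   & (rho < 0.95))
            return dihedral_angles(v, t[sel]).max()

        assert junction_wall_dihedral(s) < junction_wall_dihedral(m) - 1e-3


class TestFamily:
    def test_family_has_15_models_matching_names(self):
        specs = enumerate_family()
        assert len(specs) == 15
        assert {model_name(s) for s in specs} == FIG4_NAMES

    def test_thirty_point_rule_excludes_extremes(self):
        names = {model_name(s) for s in enumerate_family()}
        assert "40a85p" not in names
        assert "85a40p" not in names

    def test_every_spec_valid(self):
        for s in enumerate_family():
            s.validate()          # must not raise

    def test_model_names_format(self):
        assert model_name(ResectionSpec(0.85, 0.70)) == "85a70p"
        assert model_name(ResectionSpec(1.0, 1.0)) == "100a100p"
        assert model_name(ResectionSpec(0.40, 0.55)) == "40a55p"

    def test_built_family_bookkeeping(self, partition, coarse_sizes):
        models = build_family(partition, sizes=coarse_sizes)
        assert len(models) == 15
        for m in models:
            target = 0.5 * (m.spec.anterior_fraction + m.spec.posterior_fraction)
            assert abs(m.realized_residual_fraction - target) <= 0.015
            assert m.solid.boundary.as_trimesh().is_watertight


class TestComputeVolume:
    def test_unit_cube_exact(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
        f = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                      [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
                      [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]])
        assert compute_volume((v, f)) == pytest.approx(1.0)

    def test_sphere_volume_closed_form(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=2.0)
        v = compute_volume((np.asarray(sphere.vertices),
                            np.asarray(sphere.faces)))
        exact = 4.0 / 3.0 * np.pi * 8.0
        assert abs(v - exact) / exact < 0.005

    def test_inverted_orientation_flips_sign(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        v1 = compute_volume((np.asarray(sphere.vertices),
                             np.asarray(sphere.faces)))
        v2 = compute_volume((np.asarray(sphere.vertices),
                             np.asarray(sphere.faces)[:, ::-1]))
        assert v2 == pytest.approx(-v1)

    def test_open_mesh_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 2]])
        with pytest.raises(ValueError):
            compute_volume((v, f))
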