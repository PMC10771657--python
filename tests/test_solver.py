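"""FE core: meshing contracts, element oracle, patch test, contact benchmarks."""

import numpy as np
import pytest

from dlmfem.materials import IsotropicElastic
from dlmfem.solver import (AnalyticContact, LoadCase, RigidBody, StaticProblem,
                           assemble, box_mesh, default_penalty,
                           element_b_matrices, element_gradients, mesh_solids,
                           run_patch_test, run_uniaxial_block, solve_static)
from dlmfem.study import StudyConfig, build_knee_problem
from dlmfem.geometry import build_knee_geometry
from dlmfem import meshing


def hand_assembled_unit_tet_stiffness(E=1.0):
    """Independent single-element oracle for a TET4 with nu = 0.

    Reference tet (0, e_x, e_y, e_z); shape-function gradients are known in
    closed form: grad N0 = (-1,-1,-1), grad N1 = e_x, grad N2 = e_y,
    grad N3 = e_z.  With nu = 0 the material matrix is E*diag(1,1,1,.5,.5,.5)
    (engineering shear).  K = V * B^T D B with V = 1/6.
    """
    grads = np.array([[-1.0, -1.0, -1.0],
                      [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0],
                      [0.0, 0.0, 1.0]])
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    D = E * np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
    return (1.0 / 6.0) * B.T @ D @ B


class TestMeshing:
    def test_unit_cube_volume_conserved(self):
        g = np.linspace(0, 1, 3)
        mesh = box_mesh(g, g, g)
        assert np.isclose(mesh.volumes().sum(), 1.0, atol=1e-12)

    def test_halving_edge_multiplies_elements(self):
        g2 = np.linspace(0, 1, 3)
        g4 = np.linspace(0, 1, 5)
        coarse = box_mesh(g2, g2, g2)
        fine = box_mesh(g4, g4, g4)
        assert len(fine.tets) >= 4 * len(coarse.tets)

    def test_knee_mesh_region_tags(self, default_config, coarse_sizes):
        geom = build_knee_geometry(default_config, sizes=coarse_sizes)
        mesh = mesh_solids(geom, coarse_sizes)
        tags = set(np.unique(mesh.region))
        assert tags == {"femoral_cartilage_medial", "femoral_cartilage_lateral",
                        "tibial_cartilage_medial", "tibial_cartilage_lateral",
                        "meniscus_medial", "meniscus_lateral"}
        assert (mesh.volumes() > 0).all()
        # every element carries exactly one tag by construction; node sets exist
        assert len(mesh.node_sets["fixed"]) > 0
        assert len(mesh.node_sets["femur_bonded"]) > 0


class TestAssembly:
    def test_single_tet_matches_hand_oracle(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        tets = np.array([[0, 1, 2, 3]])
        from dlmfem.solver import TetraMesh
        mesh = TetraMesh(nodes=nodes, tets=tets,
                         region=np.array(["block"]))
        K, _ = assemble(mesh, {"block": IsotropicElastic(E=1.0, nu=0.0)})
        K_oracle = hand_assembled_unit_tet_stiffness(E=1.0)
        assert np.abs(K.toarray() - K_oracle).max() < 1e-10

    def test_duplicate_assembly_bit_identical(self, default_config, coarse_sizes):
        g = np.linspace(0, 1, 3)
        mesh = box_mesh(g, g, g)
        mat = {"block": IsotropicElastic(E=15.0, nu=0.3)}
        K1, _ = assemble(mesh, mat)
        K2, _ = assemble(mesh, mat)
        assert (K1 != K2).nnz == 0

    def test_zero_displacement_zero_force(self):
        g = np.linspace(0, 1, 3)
        mesh = box_mesh(g, g, g)
        K, _ = assemble(mesh, {"block": IsotropicElastic(E=15.0, nu=0.3)})
        assert np.abs(K @ np.zeros(K.shape[0])).max() == 0.0

    def test_stiffness_symmetric_positive_semidefinite(self):
        g = np.linspace(0, 1, 3)
        mesh = box_mesh(g, g, g)
        K, _ = assemble(mesh, {"block": IsotropicElastic(E=15.0, nu=0.3)})
        Kd = K.toarray()
        assert np.abs(Kd - Kd.T).max() < 1e-9 * np.abs(Kd).max()
        w = np.linalg.eigvalsh(Kd)
        assert w.min() > -1e-9 * w.max()      # six rigid-body zero modes


class TestStaticSolve:
    def test_patch_test_reproduces_constant_stress(self):
        assert run_patch_test() <= 1e-8

    def test_zero_load_zero_displacement(self):
        g = np.linspace(0, 10, 4)
        mesh = box_mesh(g, g, g)
        mesh.node_sets["fixed"] = mesh.node_sets["bottom"]
        K, _ = assemble(mesh, {"block": IsotropicElastic(E=15.0, nu=0.3)})
        prob = StaticProblem(mesh, K, [], [])
        state = solve_static(prob, LoadCase(increments=1))
        assert np.abs(state.displacements).max() == 0.0

    def test_uniaxial_block_strain_closed_form(self):
        res = run_uniaxial_block(pressure=1.0, E=15.0)
        assert res["rel_err"] <= 0.01

    def test_doubling_load_doubles_contact_force(self):
        forces = []
        for F in (50.0, 100.0):
            res = run_uniaxial_block(pressure=F / 100.0, E=15.0)
            forces.append(res)
        assert forces[1]["strain"] == pytest.approx(2 * forces[0]["strain"],
                                                    rel=2e-2)

    def test_mesh_objectivity_under_rotation(self):
        """Rotating the whole problem rotates the solution."""
        g = np.linspace(0.0, 4.0, 3)
        mesh = box_mesh(g, g, g)
        mesh.node_sets["fixed"] = mesh.node_sets["bottom"]
        mat = {"block": IsotropicElastic(E=10.0, nu=0.25)}
        K, _ = assemble(mesh, mat)
        F = np.zeros((mesh.n_nodes, 3))
        F[mesh.node_sets["top"], 2] = -1.0
        prob = StaticProblem(mesh, K, [], [], nodal_loads=F.ravel())
        u0 = solve_static(prob, LoadCase(increments=1)).displacements

        phi = 0.4
        R = np.array([[np.cos(phi), -np.sin(phi), 0],
                      [np.sin(phi), np.cos(phi), 0], [0, 0, 1.0]])
        from dlmfem.solver import TetraMesh
        mesh_r = TetraMesh(nodes=mesh.nodes @ R.T, tets=mesh.tets.copy(),
                           region=mesh.region.copy(),
                           node_sets={k: v.copy() for k, v in mesh.node_sets.items()},
                           surfaces={k: v.copy() for k, v in mesh.surfaces.items()})
        K_r, _ = assemble(mesh_r, mat)
        F_r = F @ R.T
        prob_r = StaticProblem(mesh_r, K_r, [], [], nodal_loads=F_r.ravel())
        u1 = solve_static(prob_r, LoadCase(increments=1)).displacements
        assert np.abs(u1 - u0 @ R.T).max() < 1e-6 * max(np.abs(u0).max(), 1e-12)


@pytest.fixture(scope="module")
def knee_state():
    cfg = StudyConfig()
    cfg.load_case = LoadCase(increments=2)
    geom = build_knee_geometry(cfg.geometry, cfg.sizes)
    mesh, problem, data = build_knee_problem(geom, cfg)
    state = solve_static(problem, cfg.load_case)
    return cfg, mesh, problem, state


class TestKneeContact:
    def test_global_equilibrium_within_half_percent(self, knee_state):
        cfg, mesh, problem, state = knee_state
        reaction = abs(state.reactions[:, 2].sum())
        assert abs(reaction - cfg.axial_load) / cfg.axial_load <= 0.005

    def test_penetration_within_limit(self, knee_state):
        cfg, mesh, problem, state = knee_state
        assert max(state.contact_penetration.values()) <= \
            cfg.load_case.max_penetration

    def test_symmetric_compartments_share_load_evenly(self, coarse_sizes):
        """With identical discoid menisci on both sides and no ligaments the
        medial/lateral contact split is 50/50."""
        import dataclasses
        cfg = StudyConfig()
        cfg.load_case = LoadCase(increments=2)
        cfg.geometry = dataclasses.replace(
            cfg.geometry, medial_meniscus_inner_rim_ratio=0.0,
            ligament_fiber_counts={k: 0 for k in ("ACL", "PCL", "MCL", "LCL",
                                                  "PAT")})
        geom = build_knee_geometry(cfg.geometry, cfg.sizes)
        mesh, problem, data = build_knee_problem(geom, cfg)
        state = solve_static(problem, cfg.load_case)
        med = state.contact_forces["femcart-meniscus-medial"] + \
            state.contact_forces["femcart-tibcart-medial"]
        lat = state.contact_forces["femcart-meniscus-lateral"] + \
            state.contact_forces["femcart-tibcart-lateral"]
        assert abs(med - lat) / (med + lat) < 0.02


@pytest.mark.parametrize("E,h", [(15.0, 2.0), (60.0, 1.0)])
def test_default_penalty_formula(E, h):
    assert default_penalty(E, h) == pytest.approx(50.0 * E / h)


def test_penalty_insensitivity_of_meniscus_peak(knee_state):
    """A 10x stiffer contact penalty changes the lateral-meniscus peak
    Tresca stress by at most 3% (the solution is penalty-converged)."""
    from dlmfem.postprocess import recover_stresses, region_peaks
    from dlmfem.solver import assemble as _assemble

    cfg, mesh, problem, state = knee_state
    geom = mesh.geometry
    mesh2, problem2, data2 = build_knee_problem(
        geom, cfg, penalty=10.0 * default_penalty(15.0, cfg.sizes.in_plane))
    state2 = solve_static(problem2, cfg.load_case)
    _, _, data1 = build_knee_problem(geom, cfg)
    p1 = region_peaks(recover_stresses(state, mesh, data1))
    p2 = region_peaks(recover_stresses(state2, mesh2, data2))
    assert abs(p2.tresca["LM"] - p1.tresca["LM"]) / p1.tresca["LM"] <= 0.03
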