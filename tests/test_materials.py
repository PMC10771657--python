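"""Constitutive models: closed-form checks, tensor rotations, fiber response."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dlmfem.materials import (IsotropicElastic, LinearFiber,
                              MaterialParameterError, NeoHookeanParams,
                              TransverselyIsotropicElastic,
                              compute_fiber_frames, neo_hookean_fiber_force,
                              stiffness_isotropic, stiffness_trans_iso)

VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))


def tensor_from_voigt(C):
    """Expand a 6x6 Voigt stiffness to the full 3x3x3x3 tensor (oracle)."""
    T = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(VOIGT_PAIRS):
        for J, (k, l) in enumerate(VOIGT_PAIRS):
            for a, b in {(i, j), (j, i)}:
                for c, d in {(k, l), (l, k)}:
                    T[a, b, c, d] = C[I, J]
    return T


def voigt_from_tensor(T):
    C = np.zeros((6, 6))
    for I, (i, j) in enumerate(VOIGT_PAIRS):
        for J, (k, l) in enumerate(VOIGT_PAIRS):
            C[I, J] = T[i, j, k, l]
    return C


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestIsotropic:
    def test_c1111_closed_form(self):
        C = stiffness_isotropic(IsotropicElastic(E=15.0, nu=0.3))
        expected = 15.0 * 0.7 / (1.3 * 0.4)      # E(1-nu)/((1+nu)(1-2nu))
        assert abs(C[0, 0] - expected) < 1e-3
        assert abs(C[0, 0] - 20.192) < 1e-2

    def test_zero_poisson_gives_E_on_diagonal(self):
        C = stiffness_isotropic(IsotropicElastic(E=15.0, nu=0.0))
        assert C[0, 0] == pytest.approx(15.0)

    def test_hydrostatic_response_is_bulk_modulus(self):
        E, nu = 15.0, 0.3
        C = stiffness_isotropic(IsotropicElastic(E=E, nu=nu))
        delta = 1e-3
        eps = np.array([delta, delta, delta, 0, 0, 0])
        sig = C @ eps
        K = E / (3 * (1 - 2 * nu))
        assert np.allclose(sig[:3], 3 * K * delta / 3 * 3, rtol=1e-12) or \
            np.allclose(sig[:3], 3 * K * delta, rtol=1e-12)
        assert np.allclose(sig[3:], 0.0)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(MaterialParameterError):
            stiffness_isotropic(IsotropicElastic(E=1.0, nu=0.5))


class TestTransverselyIsotropic:
    def test_degenerates_to_isotropic(self):
        E, nu = 20.0, 0.2
        mat = TransverselyIsotropicElastic(
            E_circ=E, E_plane=E, nu_plane=nu, nu_circ_plane=nu,
            G_circ_plane=E / (2 * (1 + nu)))
        C = stiffness_trans_iso(mat, np.eye(3))
        C_iso = stiffness_isotropic(IsotropicElastic(E=E, nu=nu))
        assert np.abs(C - C_iso).max() < 1e-9

    def test_s11_is_reciprocal_circumferential_modulus(self):
        mat = TransverselyIsotropicElastic()
        S = mat.compliance_local()
        assert S[0, 0] == 1.0 / 140.0

    def test_default_stiffness_spd_and_symmetric(self):
        mat = TransverselyIsotropicElastic()
        C = stiffness_trans_iso(mat, np.eye(3))
        assert np.abs(C - C.T).max() < 1e-9 * np.abs(C).max()
        assert np.linalg.eigvalsh(C).min() > 0

    def test_rotation_matches_tensor_oracle(self, rng):
        """Voigt (Bond) rotation vs brute-force 4th-order tensor rotation."""
        mat = TransverselyIsotropicElastic()
        C0 = stiffness_trans_iso(mat, np.eye(3))
        for _ in range(5):
            R = random_rotation(rng)
            # frame rows are the local axes: local = R_frame @ global
            C_rot = stiffness_trans_iso(mat, R)
            T0 = tensor_from_voigt(C0)
            # oracle: C'_{abcd} = Q_ai Q_bj Q_ck Q_dl C_{ijkl}, Q = R^T
            Q = R.T
            T_rot = np.einsum("ai,bj,ck,dl,ijkl->abcd", Q, Q, Q, Q, T0)
            assert np.abs(voigt_from_tensor(T_rot) - C_rot).max() < 1e-9 * 140

    def test_energy_invariance_under_frame_rotation(self, rng):
        mat = TransverselyIsotropicElastic()
        eps = np.array([1e-3, -2e-4, 5e-4, 3e-4, -1e-4, 2e-4])
        C0 = stiffness_trans_iso(mat, np.eye(3))
        w0 = 0.5 * eps @ C0 @ eps

        def rotate_strain(eps_v, Q):
            E = np.array([[eps_v[0], eps_v[5] / 2, eps_v[4] / 2],
                          [eps_v[5] / 2, eps_v[1], eps_v[3] / 2],
                          [eps_v[4] / 2, eps_v[3] / 2, eps_v[2]]])
            Er = Q @ E @ Q.T
            return np.array([Er[0, 0], Er[1, 1], Er[2, 2],
                             2 * Er[1, 2], 2 * Er[0, 2], 2 * Er[0, 1]])

        for _ in range(3):
            R = random_rotation(rng)
            C_rot = stiffness_trans_iso(mat, R)       # frame rotated
            eps_rot = rotate_strain(eps, R.T)         # strain co-rotated
            w1 = 0.5 * eps_rot @ C_rot @ eps_rot
            assert abs(w1 - w0) < 1e-8 * abs(w0)

    def test_thermodynamic_restriction_enforced(self):
        bad = TransverselyIsotropicElastic(E_circ=10.0, E_plane=100.0,
                                           nu_circ_plane=0.9)
        with pytest.raises(MaterialParameterError):
            bad.validate()


class TestFiberFrames:
    def test_circular_disc_matches_azimuth(self):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        margin = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        rng = np.random.default_rng(3)
        r = np.sqrt(rng.uniform(0.1, 0.9, 100)) * 10
        a = rng.uniform(0, 2 * np.pi, 100)
        cents = np.column_stack([r * np.cos(a), r * np.sin(a), np.zeros(100)])
        frames = compute_fiber_frames(cents, margin)
        azim = np.column_stack([-np.sin(a), np.cos(a), np.zeros(100)])
        dots = np.abs(np.einsum("id,id->i", frames[:, 0], azim))
        assert np.all(np.degrees(np.arccos(np.clip(dots, -1, 1))) < 2.0)

    def test_triads_orthonormal_and_right_handed(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        margin = np.column_stack([15 * np.cos(th), 17 * np.sin(th)])
        cents = np.array([[3.0, 4.0, 1.0], [-8.0, 2.0, 0.5], [0.01, 0.0, 0.0]])
        frames = compute_fiber_frames(cents, margin)
        for F in frames:
            assert np.abs(F @ F.T - np.eye(3)).max() < 1e-10
            assert np.linalg.det(F) > 0

    def test_frames_rotate_with_the_margin(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        margin = np.column_stack([15 * np.cos(th), 10 * np.sin(th)])
        cents = np.array([[5.0, 2.0, 0.0], [-4.0, -6.0, 1.0]])
        phi = 0.7
        Rz = np.array([[np.cos(phi), -np.sin(phi), 0],
                       [np.sin(phi), np.cos(phi), 0], [0, 0, 1.0]])
        frames = compute_fiber_frames(cents, margin)
        frames_rot = compute_fiber_frames(cents @ Rz.T, margin @ Rz[:2, :2].T)
        for F, Fr in zip(frames, frames_rot):
            circ_expected = Rz @ F[0]
            assert np.abs(np.abs(circ_expected @ Fr[0]) - 1.0) < 1e-6


class TestFibers:
    def test_zero_force_at_reference(self):
        mat = NeoHookeanParams(C1=5.08, D1=0.00683)
        assert neo_hookean_fiber_force(mat, 1.0, 40.0) == 0.0

    def test_small_strain_modulus_is_six_c1(self):
        """d(sigma)/d(lambda) at lambda=1 equals 6 C1 (ACL: 30.48 MPa)."""
        mat = NeoHookeanParams(C1=5.08, D1=0.00683, tension_only=False)
        h = 1e-6
        slope = (mat.cauchy_uniaxial(1 + h) - mat.cauchy_uniaxial(1 - h)) / (2 * h)
        assert abs(slope - 6 * 5.08) / (6 * 5.08) < 1e-3
        assert abs(6 * 5.08 - 30.48) < 1e-9

    def test_tension_only_flag(self):
        mat = NeoHookeanParams(C1=5.08, D1=0.00683)
        assert neo_hookean_fiber_force(mat, 1.1, 1.0) > 0
        assert neo_hookean_fiber_force(mat, 0.9, 1.0) == 0.0
        both = NeoHookeanParams(C1=5.08, D1=0.00683, tension_only=False)
        assert neo_hookean_fiber_force(both, 0.9, 1.0) < 0

    @given(st.floats(min_value=0.51, max_value=1.99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_stretch(self, lam):
        mat = NeoHookeanParams(C1=6.06, D1=0.0041, tension_only=False)
        h = 1e-4
        assert (mat.cauchy_uniaxial(lam + h) > mat.cauchy_uniaxial(lam))

    def test_energy_density_compressible_form(self):
        mat = NeoHookeanParams(C1=2.0, D1=0.01)
        F = np.diag([1.1, 0.97, 0.96])
        J = np.linalg.det(F)
        I1 = (F ** 2).sum()
        expected = 2.0 * (I1 * J ** (-2 / 3) - 3) + (1 / 0.01) * (J - 1) ** 2
        assert mat.energy_density(F) == pytest.approx(expected)
        assert mat.energy_density(np.eye(3)) == pytest.approx(0.0)

    def test_domain_errors(self):
        mat = NeoHookeanParams(C1=5.08, D1=0.00683)
        with pytest.raises(ValueError):
            neo_hookean_fiber_force(mat, -0.5, 1.0)

    def test_linear_fiber(self):
        f = LinearFiber(E=60.0)
        assert f.force(1.01, 40.0) == pytest.approx(60.0 * 40.0 * 0.01)
        assert f.force(0.99, 40.0) == 0.0
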