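"""Upscaled continuum: kinematics, constitutive law, energy minimization and
the strong-form verification."""

import math

import numpy as np
import pytest

from corneasim.continuum import (
    ContinuumModel,
    ContinuumSolverOptions,
    DeformationField,
    fiber_frame,
    right_cauchy_green,
    second_pk_stress,
    strain_energy_density,
    strong_form_residual,
    total_potential,
)
from corneasim.damage import DamageSpec
from corneasim.discrete import MaterialSpec
from corneasim.errors import CorneaSimError
from corneasim.fixtures import make_fixture
from corneasim.geometry import CorneaGeometry

KAPPA = 2 * 0.825099632 / 20.0  # baseline kappa
R_MID = 12.0  # a dimensionless radius inside the baseline sector


class TestFiberFrame:
    def test_unit_vectors_and_angle(self):
        fr = fiber_frame(R_MID, KAPPA)
        for e in (fr.e_R, fr.e_Phi, fr.e_plus, fr.e_minus):
            assert np.linalg.norm(e) == pytest.approx(1.0, abs=1e-14)
        assert fr.beta == pytest.approx(math.atan(1.0 / (KAPPA * R_MID)), abs=1e-14)
        assert fr.e_plus @ fr.e_minus == pytest.approx(
            math.sin(fr.beta) ** 2 - math.cos(fr.beta) ** 2, abs=1e-14
        )


class TestRightCauchyGreen:
    def test_identity_field(self):
        C = right_cauchy_green(DeformationField.identity(), (R_MID, 0.1))
        assert np.allclose(C, np.eye(2), atol=1e-12)

    def test_uniform_inflation(self):
        c = 1.07
        f = DeformationField(
            r_fn=lambda R, P: c * R,
            phi_fn=lambda R, P: P,
            grad_fn=lambda R, P: (c, 0.0, 0.0, 1.0),
        )
        C = right_cauchy_green(f, (R_MID, -0.2))
        assert np.allclose(C, c**2 * np.eye(2), atol=1e-12)

    def test_manufactured_shear_field(self):
        a = 0.05
        f = make_fixture("manufactured_field", a=a)
        C = right_cauchy_green(f, (R_MID, 0.3))
        lam_Phi = math.sqrt(C[1, 1])
        lam_R = math.sqrt(C[0, 0])
        assert lam_Phi == pytest.approx(1.0, abs=1e-12)
        assert lam_R == pytest.approx(math.sqrt(1 + a**2 * R_MID**2), rel=1e-12)

    def test_finite_difference_gradient_fallback(self):
        f_an = make_fixture("manufactured_field", a=0.03)
        f_fd = DeformationField(r_fn=f_an.r_fn, phi_fn=f_an.phi_fn)
        C1 = right_cauchy_green(f_an, (R_MID, 0.2))
        C2 = right_cauchy_green(f_fd, (R_MID, 0.2))
        assert np.allclose(C1, C2, atol=1e-8)


def _random_spd_C(rng, spread=0.1):
    A = np.eye(2) + spread * rng.standard_normal((2, 2))
    return A.T @ A


class TestConstitutiveLaw:
    def test_energy_zero_at_identity(self):
        assert strain_energy_density(np.eye(2), R_MID, KAPPA) == pytest.approx(0.0, abs=1e-15)

    def test_stress_zero_at_identity(self):
        T = second_pk_stress(np.eye(2), R_MID, KAPPA)
        assert (T.T_RR, T.T_RPhi, T.T_PhiPhi) == (0.0, 0.0, 0.0)

    def test_pure_azimuthal_stretch_hand_value(self):
        """lam along e_Phi only: lam_pm = sqrt(sin^2 b + lam^2 cos^2 b)."""
        lam = 1.01
        R = 12.580645161  # anterior dimensionless radius
        C = np.diag([1.0, lam**2])
        fr = fiber_frame(R, KAPPA)
        sb, cb = math.sin(fr.beta), math.cos(fr.beta)
        lam_pm = math.sqrt(sb**2 + lam**2 * cb**2)
        kR = KAPPA * R
        K3 = 0.07
        expected = (
            kR**2 * 1.0 * (lam - 1) ** 2 + 2 * (1 + kR**2) * K3 * (lam_pm - 1) ** 2
        ) / (2 * KAPPA * R * 1.0)
        got = strain_energy_density(C, R, KAPPA, K1=1.0, K2=0.001, K3=K3, D=1.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_shear_stress_sign(self):
        """Stretching e_plus more than e_minus gives positive T_RPhi."""
        C = np.array([[1.0, 0.02], [0.02, 1.0]])  # positive RPhi shear
        T = second_pk_stress(C, R_MID, KAPPA)
        assert T.T_RPhi > 0

    def test_stress_is_twice_energy_derivative(self):
        """T = 2 dW/dC against a central-difference oracle at random SPD C."""
        rng = np.random.default_rng(7)
        h = 1e-7
        for _ in range(5):
            C = _random_spd_C(rng)
            T = second_pk_stress(C, R_MID, KAPPA, K1=1.0, K2=0.001, K3=0.07).as_matrix()
            T_fd = np.zeros((2, 2))
            for a in range(2):
                for b in range(2):
                    dC = np.zeros((2, 2))
                    # symmetric perturbation (C is symmetric)
                    dC[a, b] += 0.5 * h
                    dC[b, a] += 0.5 * h
                    Wp = strain_energy_density(C + dC, R_MID, KAPPA, K2=0.001, K3=0.07)
                    Wm = strain_energy_density(C - dC, R_MID, KAPPA, K2=0.001, K3=0.07)
                    T_fd[a, b] = 2 * (Wp - Wm) / (2 * h)
            assert np.allclose(T, T_fd, rtol=1e-6, atol=1e-10)

    def test_frame_indifference(self):
        """W computed from F and from Q F (rigid rotation Q) agree, since
        both produce the same C."""
        rng = np.random.default_rng(11)
        F = np.eye(2) + 0.05 * rng.standard_normal((2, 2))
        th = 0.7
        Q = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        W1 = strain_energy_density(F.T @ F, R_MID, KAPPA)
        W2 = strain_energy_density((Q @ F).T @ (Q @ F), R_MID, KAPPA)
        assert W1 == pytest.approx(W2, rel=1e-13)

    def test_non_spd_C_rejected(self):
        with pytest.raises(CorneaSimError):
            strain_energy_density(np.diag([1.0, -0.5]), R_MID, KAPPA)


class TestTotalPotential:
    def test_identity_at_zero_pressure(self, baseline_geom, baseline_material):
        m = ContinuumModel(baseline_geom, baseline_material, gamma=20.0, n_R=4, n_Phi=12)
        assert total_potential(m, m.identity_state(), p=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_gradient_matches_finite_differences(self, baseline_geom, baseline_material):
        """The assembled gradient (elastic + follower pressure) is the
        derivative of the total potential at the free dofs."""
        m = ContinuumModel(baseline_geom, baseline_material, gamma=20.0, n_R=4, n_Phi=12)
        rng = np.random.default_rng(1)
        u = m.identity_state()
        u[:, 0] += 0.01 * rng.standard_normal(m.n_nodes)
        u[:, 1] += 0.001 * rng.standard_normal(m.n_nodes)
        p = 10 * m.p_target  # exaggerate the pressure part
        G = m.gradient(u, p)
        h = 1e-6
        for d in rng.choice(m.free_dofs, 40, replace=False):
            up = u.copy()
            up.ravel()[d] += h
            um = u.copy()
            um.ravel()[d] -= h
            fd = (m.energy(up, p) - m.energy(um, p)) / (2 * h)
            assert G[d] == pytest.approx(fd, rel=5e-5, abs=1e-11)

    def test_hessian_matches_finite_differences(self, baseline_geom, baseline_material):
        m = ContinuumModel(baseline_geom, baseline_material, gamma=20.0, n_R=3, n_Phi=8)
        rng = np.random.default_rng(2)
        u = m.identity_state()
        u[:, 0] += 0.01 * rng.standard_normal(m.n_nodes)
        u[:, 1] += 0.001 * rng.standard_normal(m.n_nodes)
        p = m.p_target
        H = m.hessian(u, p)
        h = 1e-6
        for d in rng.choice(m.free_dofs, 12, replace=False):
            up = u.copy()
            up.ravel()[d] += h
            um = u.copy()
            um.ravel()[d] -= h
            fd = (m.gradient(up, p) - m.gradient(um, p)) / (2 * h)
            col = np.asarray(H[:, d].todense()).ravel()
            assert np.allclose(
                fd[m.free_dofs], col[m.free_dofs], atol=1e-6 * max(1.0, np.abs(col).max())
            )


class TestSolve:
    def test_zero_pressure_identity(self, baseline_geom):
        mat = MaterialSpec(p=0.0)
        m = ContinuumModel(baseline_geom, mat, gamma=20.0, n_R=4, n_Phi=12)
        sol = m.solve()
        kk = np.arange(m.n_nodes) % (m.n_R + 1)
        ll = np.arange(m.n_nodes) // (m.n_R + 1)
        assert np.max(np.abs(sol.r - m.R[:, None])) < 1e-12
        assert np.max(np.abs(sol.phi - m.Phi[None, :])) < 1e-12
        assert sol.energy == pytest.approx(0.0, abs=1e-18)

    def test_healthy_solution_mirror_symmetry(self, coarse_continuum):
        sol = coarse_continuum(n_R=8)
        assert np.max(np.abs(sol.r - sol.r[:, ::-1])) < 1e-9
        assert np.max(np.abs(sol.phi + sol.phi[:, ::-1])) < 1e-9

    def test_damaged_solution_mirror_symmetry(self, coarse_continuum, baseline_geom):
        dmg = DamageSpec(Dmax=0.9, xi=4, Y_max=baseline_geom.Y_max)
        sol = coarse_continuum(n_R=8, damage=dmg)
        assert np.max(np.abs(sol.r - sol.r[:, ::-1])) < 1e-8

    def test_det_F_positive_everywhere(self, coarse_continuum):
        sol = coarse_continuum(n_R=8)
        r_R = np.gradient(sol.r, sol.R, axis=0)
        r_P = np.gradient(sol.r, sol.Phi, axis=1)
        p_R = np.gradient(sol.phi, sol.R, axis=0)
        p_P = np.gradient(sol.phi, sol.Phi, axis=1)
        detF = sol.r * (r_R * p_P - r_P * p_R) / sol.R[:, None]
        assert np.all(detF > 0)

    def test_energy_decreases_with_pressure_work(self, coarse_continuum):
        # the loaded equilibrium has negative total potential (pressure does work)
        sol = coarse_continuum(n_R=8)
        assert sol.energy < 0

    def test_solve_continuum_from_config(self):
        from corneasim.config import load_config
        from corneasim.continuum import solve_continuum

        cfg = load_config({"continuum": {"n_R": 4, "n_Phi": 12}})
        sol = solve_continuum(cfg, healthy=True)
        assert sol.n_R == 4 and sol.n_Phi == 12
        assert sol.grad_norm <= 1e-10


class TestStrongForm:
    def test_identity_residual_zero(self, baseline_geom, baseline_material):
        m = ContinuumModel(baseline_geom, baseline_material, gamma=20.0, n_R=8)
        mat0 = MaterialSpec(p=0.0)
        m0 = ContinuumModel(baseline_geom, mat0, gamma=20.0, n_R=8)
        sol = m0.solve()
        res_r, res_phi = strong_form_residual(sol)
        assert np.max(np.abs(res_r)) < 1e-12
        assert np.max(np.abs(res_phi)) < 1e-12

    @staticmethod
    def _mean_relative_residual(sol):
        """Mean of |residual| / (pointwise dominant term magnitude)."""
        kap, R, Phi, r, phi = sol.kappa, sol.R, sol.Phi, sol.r, sol.phi
        K2, K3 = sol.material.K2_ratio(), sol.material.K3_ratio()
        ddR = lambda f: np.gradient(f, R, axis=0)
        ddP = lambda f: np.gradient(f, Phi, axis=1)
        r_R, r_P, p_R, p_P = ddR(r), ddP(r), ddR(phi), ddP(phi)
        w = 1 / np.sqrt(1 + (kap * R[:, None]) ** 2)
        q = 1 / (kap * R[:, None])
        lam_P = q * np.hypot(kap * r_P, kap * r * p_P)
        lam_R = np.hypot(r_R, r * p_R)
        lam_p = w * np.hypot(r_R + kap * r_P, r * p_R + kap * r * p_P)
        lam_m = w * np.hypot(r_R - kap * r_P, r * p_R - kap * r * p_P)
        G1, G2 = (1 - 1 / lam_P), K2 * (1 - 1 / lam_R)
        Gp, Gm = K3 * (1 - 1 / lam_p), K3 * (1 - 1 / lam_m)
        terms = [
            kap**2 * (ddP(r_P * G1) - r * p_P**2 * G1),
            ddR(r_R * G2) - r * p_R**2 * G2,
            ddR((r_R + kap * r_P) * Gp + (r_R - kap * r_P) * Gm),
            kap * ddP((r_R + kap * r_P) * Gp - (r_R - kap * r_P) * Gm),
            -(p_R + kap * p_P) * (r * p_R + kap * r * p_P) * Gp,
            -(p_R - kap * p_P) * (r * p_R - kap * r * p_P) * Gm,
        ]
        scale = np.max([np.abs(t[1:-1, 1:-1]) for t in terms], axis=0)
        res_r, _ = strong_form_residual(sol)
        return float((np.abs(res_r) / np.maximum(scale, 1e-30)).mean())

    def test_interior_residual_small_and_decreasing(self, baseline_geom, baseline_material):
        """The energy minimizer satisfies the strong-form balance: the mean
        interior residual, relative to the pointwise dominant term of the
        radial balance, is a few percent and decreases ~O(1/N) under grid
        refinement (self-convergence)."""
        norms = []
        for n_R in (8, 16):
            m = ContinuumModel(baseline_geom, baseline_material, gamma=20.0, n_R=n_R)
            sol = m.solve()
            norms.append(self._mean_relative_residual(sol))
        assert norms[1] < 0.6 * norms[0]
        assert norms[1] < 0.05
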