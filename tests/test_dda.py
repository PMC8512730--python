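"""Coupled-dipole engine tests: polarizabilities, interaction products,
solvers, far fields, Mueller matrices, and cross sections."""

import math

import numpy as np
import pytest

import chiroscat as cs
from chiroscat import dda


K300 = 2.0 * math.pi * 1.33 / 300.0


def _single_dipole(rel_index=1.68 / 1.33, spacing=1.0):
    return cs.DipoleModel(
        spacing=spacing, origin=np.zeros(3), sites=np.array([[0, 0, 0]]), rel_index=rel_index
    )


class TestPolarizability:
    @pytest.mark.parametrize(
        "m, d, expected",
        [
            (1.0, 1.0, 0.0),
            (complex(math.sqrt(2.0)), 1.0, 3.0 / (16.0 * math.pi)),
            (1.68 / 1.33, 1.0, 0.0395435),  # direct evaluation of the closed form
        ],
    )
    def test_clausius_mossotti_closed_form(self, m, d, expected):
        assert cs.cm_polarizability(m, d) == pytest.approx(expected, rel=1e-4, abs=1e-12)

    def test_cm_resonance_is_error(self):
        with pytest.raises(ValueError):
            cs.cm_polarizability(complex(0, math.sqrt(2.0)), 1.0)  # m^2 = -2

    def test_ldr_reduces_to_cm_in_long_wavelength_limit(self, default_wave):
        m, d = 1.2632, 1.0
        long_wave = cs.PlaneWave(lambda_vac=3.0e7)
        assert cs.ldr_polarizability(m, d, long_wave) == pytest.approx(
            cs.cm_polarizability(m, d), rel=1e-8
        )

    def test_ldr_keeps_exact_radiative_reaction(self, default_wave):
        """Im(1/alpha) = -(2/3) k^3 for real m: one dipole scatters, never absorbs."""
        alpha = cs.ldr_polarizability(1.2632, 1.0, default_wave)
        k = default_wave.k
        assert np.imag(1.0 / alpha) == pytest.approx(-(2.0 / 3.0) * k**3, rel=1e-12)

    def test_ldr_finite_and_continuous_in_kd(self):
        vals = []
        for lam in np.linspace(80.0, 3000.0, 40):
            w = cs.PlaneWave(lambda_vac=lam)
            vals.append(cs.ldr_polarizability(1.2632, 1.0, w))
        vals = np.array(vals)
        assert np.all(np.isfinite(vals))
        assert np.abs(np.diff(vals)).max() < 0.05 * np.abs(vals).max()


class TestInteraction:
    def test_single_site_no_self_term(self):
        model = _single_dipole()
        out = cs.apply_interaction(model, K300, np.array([[1.0, 0.0, 0.0]]), method="direct")
        np.testing.assert_array_equal(out, 0.0)

    def test_two_site_longitudinal_closed_form(self):
        """Field along the separation axis follows 2(1-ikr)e^{ikr}/r^3."""
        r = 4.0
        model = cs.DipoleModel(
            spacing=r, origin=np.zeros(3), sites=np.array([[0, 0, 0], [0, 0, 1]]), rel_index=1.2632
        )
        P = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]], dtype=complex)
        out = cs.apply_interaction(model, K300, P, method="direct")
        expected = 2.0 * (1.0 - 1j * K300 * r) * np.exp(1j * K300 * r) / r**3
        assert out[1, 2] == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(out[1, :2], 0.0, atol=1e-15)
        np.testing.assert_allclose(out[0], 0.0, atol=1e-15)  # P_1 = 0 radiates nothing

    def test_accelerated_matches_direct(self, random_lattice_model):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(50, 3)) + 1j * rng.normal(size=(50, 3))
        fd = cs.apply_interaction(random_lattice_model, K300, P, method="direct")
        fa = cs.apply_interaction(random_lattice_model, K300, P, method="accelerated")
        assert np.abs(fa - fd).max() / np.abs(fd).max() <= 1e-10

    def test_coincident_sites_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cs.DipoleModel(
                spacing=1.0, origin=np.zeros(3), sites=np.array([[0, 0, 0], [0, 0, 0]]), rel_index=1.2
            )


class TestSolvers:
    def test_single_dipole_solution_is_alpha_e(self, default_wave):
        model = _single_dipole()
        sol = cs.solve_dipoles(model, default_wave)
        alpha = cs.ldr_polarizability(model.rel_index, model.spacing, default_wave)
        np.testing.assert_allclose(sol.P, alpha * sol.E_inc, rtol=1e-12)

    def test_two_dipole_matches_closed_form(self, default_wave):
        sep = np.array([0.0, 0.0, 3.0])
        model = cs.DipoleModel(
            spacing=3.0, origin=np.zeros(3), sites=np.array([[0, 0, 0], [0, 0, 1]]), rel_index=1.2632
        )
        alpha = cs.ldr_polarizability(1.2632, 3.0, default_wave)
        p_ref, _ = cs.two_dipole_closed_form(sep, alpha, default_wave)
        sol = cs.solve_dipoles(model, default_wave, tol=1e-10)
        assert np.abs(sol.P - p_ref).max() / np.abs(p_ref).max() <= 1e-9

    def test_residual_contract_reverifiable(self, mini_helix_model, default_wave):
        sol = cs.solve_dipoles(mini_helix_model, default_wave, tol=1e-6)
        assert sol.residual <= 1e-6
        field = cs.apply_interaction(mini_helix_model, default_wave.k, sol.P)
        alpha = sol.alpha[:, None]
        lhs = sol.P - alpha * (sol.E_inc + field)
        rel = np.linalg.norm(lhs) / np.linalg.norm(alpha * sol.E_inc)
        assert rel == pytest.approx(sol.residual, rel=1e-6, abs=1e-12)

    def test_iterative_matches_dense_solve(self, default_wave):
        spec = cs.SolenoidSpec()
        model = cs.voxelize(cs.nucleosome_poses(spec), spec.shape, 7)
        assert model.n_dipoles <= 200
        tol = 1e-8
        it = cs.solve_dipoles(model, default_wave, tol=tol)
        dn = dda.solve_dipoles_dense(model, default_wave)
        assert np.abs(it.P - dn.P).max() / np.abs(dn.P).max() <= tol

    def test_born_mode(self, mini_helix_model, default_wave):
        sol = cs.born_dipoles(mini_helix_model, default_wave)
        np.testing.assert_allclose(sol.P, sol.alpha[:, None] * sol.E_inc, rtol=1e-14)
        assert sol.residual == 0.0  # exact for the uncoupled equation
        single = _single_dipole()
        np.testing.assert_allclose(
            cs.born_dipoles(single, default_wave).P,
            cs.solve_dipoles(single, default_wave).P,
            rtol=1e-12,
        )


class TestFarField:
    def test_single_dipole_rayleigh_pattern(self, default_wave):
        model = _single_dipole()
        theta = np.arange(0.0, 360.0, 5.0)
        sol_x = cs.solve_dipoles(model, cs.PlaneWave(jones=[1.0, 0.0]))
        sol_y = cs.solve_dipoles(model, cs.PlaneWave(jones=[0.0, 1.0]))
        amps = cs.amplitude_set(model, sol_x, sol_y, theta)
        s2, s3, s4, s1 = amps.S[:, 0, 0], amps.S[:, 0, 1], amps.S[:, 1, 0], amps.S[:, 1, 1]
        np.testing.assert_allclose(s3, 0.0, atol=1e-16)
        np.testing.assert_allclose(s4, 0.0, atol=1e-16)
        np.testing.assert_allclose(s1, s1[0], rtol=1e-12)
        np.testing.assert_allclose(s2, s1[0] * np.cos(np.deg2rad(theta)), atol=1e-12 * np.abs(s1[0]))

    def test_rigid_translation_leaves_mueller_unchanged(self, default_wave):
        spec = cs.SolenoidSpec()
        model = cs.voxelize(cs.nucleosome_poses(spec), spec.shape, 8)
        shifted = cs.DipoleModel(
            spacing=model.spacing,
            origin=model.origin + np.array([3.7, -1.2, 9.0]),
            sites=model.sites,
            rel_index=model.rel_index,
        )
        theta = np.arange(0.0, 360.0, 10.0)
        r0 = cs.scattering_run(model, theta_deg=theta, tol=1e-8)
        r1 = cs.scattering_run(shifted, theta_deg=theta, tol=1e-8)
        np.testing.assert_allclose(r1.mueller.matrices, r0.mueller.matrices, rtol=1e-6, atol=1e-12)

    def test_global_phase_drops_out_of_mueller(self):
        theta = np.array([0.0, 40.0, 155.0])
        rng = np.random.default_rng(3)
        S = rng.normal(size=(3, 2, 2)) + 1j * rng.normal(size=(3, 2, 2))
        m0 = cs.mueller_from_amplitudes(dda.AmplitudeSet(theta, S))
        m1 = cs.mueller_from_amplitudes(dda.AmplitudeSet(theta, np.exp(1j * 0.83) * S))
        np.testing.assert_allclose(m1.matrices, m0.matrices, rtol=1e-12)

    def test_mueller_positivity_bound(self, mini_helix_model):
        run = cs.scattering_run(mini_helix_model, theta_deg=np.arange(0.0, 360.0, 5.0), tol=1e-6)
        m = run.mueller.matrices
        assert np.all(m[:, 0, 0] >= np.abs(m).max(axis=(1, 2)) - 1e-12 * m[:, 0, 0])

    def test_isotropic_dipole_has_zero_m14(self, default_wave):
        model = _single_dipole()
        run = cs.scattering_run(model, theta_deg=np.arange(0.0, 360.0, 5.0))
        np.testing.assert_allclose(run.mueller.m14, 0.0, atol=1e-16 * run.mueller.m11.max())

    def test_reciprocity_of_m11(self):
        """m11 is invariant under exchanging (reversed) incidence and scattering
        directions; checked via an equivalent particle rotation."""
        rng = np.random.default_rng(11)
        sites = np.stack(np.unravel_index(rng.choice(6**3, 5, replace=False), (6, 6, 6)), axis=1)
        model = cs.DipoleModel(spacing=2.0, origin=np.zeros(3), sites=sites, rel_index=1.2632)
        theta0 = 50.0
        grid = np.array([theta0, 360.0 - theta0])
        fwd = cs.scattering_run(model, theta_deg=grid, tol=1e-10)
        frame = cs.euler_zyz(0.0, math.pi - math.radians(theta0), 0.0)
        rev = cs.scattering_run(model, theta_deg=grid, tol=1e-10, frame=frame)
        assert rev.mueller.m11[1] == pytest.approx(fwd.mueller.m11[0], rel=1e-6)


class TestCrossSections:
    def test_optical_theorem_single_dipole(self, default_wave):
        model = _single_dipole()
        sol = cs.solve_dipoles(model, default_wave)
        c = dda.cross_sections(model, default_wave, sol)
        integrated = dda.scattered_power(model, default_wave, sol)
        assert c.C_ext == pytest.approx(integrated, rel=1e-6)
        assert abs(c.C_abs) <= 1e-12 * c.C_ext

    def test_energy_conservation_small_model(self, mini_helix_model, default_wave):
        sol = cs.solve_dipoles(mini_helix_model, default_wave, tol=1e-8)
        c = dda.cross_sections(mini_helix_model, default_wave, sol)
        integrated = dda.scattered_power(mini_helix_model, default_wave, sol)
        assert abs((c.C_ext - c.C_abs) - integrated) / integrated <= 0.01

    def test_no_absorption_for_real_index(self, mini_helix_model, default_wave):
        sol = cs.solve_dipoles(mini_helix_model, default_wave, tol=1e-8)
        c = dda.cross_sections(mini_helix_model, default_wave, sol)
        assert abs(c.C_abs) / c.C_ext <= 1e-3
        assert c.C_ext == pytest.approx(c.C_sca + c.C_abs, rel=1e-12)

    def test_unconverged_solution_rejected(self, mini_helix_model, default_wave):
        sol = cs.solve_dipoles(mini_helix_model, default_wave, tol=1e-6)
        sol.residual, sol.tol = 1.0, 1e-6  # simulate an unconverged run
        with pytest.raises(ValueError, match="converged"):
            dda.cross_sections(mini_helix_model, default_wave, sol)
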