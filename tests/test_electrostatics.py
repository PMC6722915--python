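"""Charge profile, self-energy, Donnan potential and Coulomb pressure."""

import math

import numpy as np
import pytest

from nemadischarge import electrostatics as es
from nemadischarge.exceptions import DomainError


# ---------------------------------------------------------------------------
# screening length
# ---------------------------------------------------------------------------

class TestScreeningLength:
    def test_identity_units(self):
        t = es.IonTransport(n0=1, mu=1, D=1, eps=1, e=1)
        assert es.screening_length(t) == pytest.approx(1.0, rel=1e-15)

    def test_square_root_scaling_in_density(self):
        t1 = es.IonTransport(n0=2.5, mu=3.0, D=0.7, eps=1.1, e=1.0)
        t4 = es.IonTransport(n0=10.0, mu=3.0, D=0.7, eps=1.1, e=1.0)
        assert es.screening_length(t4) == pytest.approx(2 * es.screening_length(t1), rel=1e-12)

    def test_si_round_trip(self):
        # physiological-scale H+ transport constants; algebraic round trip
        t = es.IonTransport(n0=1.2e27, mu=3.62e-7, D=9.31e-9, eps=7.08e-10)
        lam = es.screening_length(t)
        assert lam > 0
        assert lam**2 * t.eps * t.D == pytest.approx(t.mu * t.e * t.n0, rel=1e-12)

    @pytest.mark.parametrize("field", ["n0", "mu", "D", "eps", "e"])
    def test_nonpositive_field_rejected(self, field):
        kw = dict(n0=1.0, mu=1.0, D=1.0, eps=1.0, e=1.0)
        kw[field] = 0.0
        with pytest.raises(DomainError, match=field):
            es.IonTransport(**kw)


# ---------------------------------------------------------------------------
# linearized profile
# ---------------------------------------------------------------------------

class TestLinearizedProfile:
    def test_surface_value_and_efolding(self):
        t = es.IonTransport(n0=3.0, mu=1.0, D=1.0, eps=1.0, e=2.0)
        geom = es.CapsuleGeometry(R=5.0)
        prof = es.linearized_profile(t, geom)
        lam = es.screening_length(t)
        assert prof.density(geom.R) == pytest.approx(-t.e * t.n0, rel=1e-14)
        assert prof.density(geom.R - 1 / lam) == pytest.approx(-t.e * t.n0 / math.e, rel=1e-14)

    def test_magnitude_decays_inward(self):
        prof = es.ChargeProfile("linearized", -1.0, 4.0, 1.0, 1.0)
        r = np.linspace(0, 1, 100)
        mag = np.abs(prof.density(r))
        assert np.all(np.diff(mag) > 0)  # |rho| grows toward the surface

    def test_total_charge_shell_limit(self):
        # X >> 1: all charge in a layer of thickness 1/lam -> Q ~ 4 pi R^2 rho0/lam
        prof = es.ChargeProfile("linearized", -2.0, 250.0, 1.0, 1.0)
        q_shell = 4 * math.pi * prof.R**2 * prof.rho0 / prof.lam
        assert prof.total_charge() == pytest.approx(q_shell, rel=0.01)

    def test_volume_consistency(self):
        geom = es.CapsuleGeometry(R=2.0)
        assert geom.volume == pytest.approx(4 / 3 * math.pi * 8, rel=1e-12)


# ---------------------------------------------------------------------------
# nonlinear screening BVP
# ---------------------------------------------------------------------------

class TestDimensionlessProfile:
    def test_null_solution(self):
        sol = es.solve_dimensionless_profile(5.0, 0.0, 64)
        assert np.all(sol.ys == 0)

    def test_discrete_residual_self_consistency(self):
        sol = es.solve_dimensionless_profile(5.0, -0.5, 256)
        assert sol.residual() < 1e-8

    def test_strong_depletion_default_surface(self):
        sol = es.solve_dimensionless_profile(8.0, n_grid=512)
        assert sol.ys[-1] == pytest.approx(-0.99)
        assert np.all(sol.ys > -1) and np.all(sol.ys <= 0)
        # |y| non-increasing from the surface inward
        assert np.all(np.diff(np.abs(sol.ys)) >= -1e-12)

    def test_small_amplitude_matches_regular_helmholtz_mode(self):
        # linearization of the screening equation: y ~ y_s * (X sinh x)/(x sinh X)
        X, ys_surf = 5.0, -0.01
        sol = es.solve_dimensionless_profile(X, ys_surf, 512)
        x = sol.xs[1:]
        ref = ys_surf * X * np.sinh(x) / (x * np.sinh(X))
        assert np.max(np.abs(sol.ys[1:] / ref - 1)) < 0.01

    def test_large_capsule_near_surface_exponential(self):
        # for X >> 1 the near-surface profile approaches the planar
        # exponential decay exp(-(X-x)) within the curvature factor X/x
        X, ys_surf = 50.0, -0.001
        sol = es.solve_dimensionless_profile(X, ys_surf, 4096)
        sel = sol.xs >= X - 2
        ref = ys_surf * np.exp(-(X - sol.xs[sel]))
        assert np.max(np.abs(sol.ys[sel] / ref - 1)) < 0.05

    def test_regularity_at_centre(self):
        sol = es.solve_dimensionless_profile(3.0, -0.5, 512)
        h = sol.xs[1] - sol.xs[0]
        assert abs(sol.ys[1] - sol.ys[0]) / h < 0.05 * abs(sol.y_surface)

    @pytest.mark.parametrize(
        "X,ys,ng", [(0.0, -0.5, 64), (5.0, -1.0, 64), (5.0, 0.5, 64), (5.0, -0.5, 8)]
    )
    def test_domain_errors(self, X, ys, ng):
        with pytest.raises(DomainError):
            es.solve_dimensionless_profile(X, ys, ng)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

class TestCoulombEnergy:
    def test_homogeneous_classical_value(self):
        prof = es.homogeneous_profile(1.0, 1.0, 1.0)
        assert es.coulomb_energy(prof) == pytest.approx(4 * math.pi / 15, rel=1e-14)
        assert es.coulomb_energy_numeric(prof, 100_000) == pytest.approx(
            4 * math.pi / 15, rel=1e-4
        )

    def test_shell_classical_value(self):
        prof = es.shell_profile(1.0, 1.0, 1.0)
        Q = prof.total_charge()
        assert es.coulomb_energy(prof) == pytest.approx(Q**2 / (8 * math.pi), rel=1e-14)

    def test_small_X_fixed_charge_approaches_homogeneous(self):
        X = 1e-3
        prof = es.ChargeProfile("linearized", 1.0, X, 1.0, 1.0)
        Q = prof.total_charge()
        U_hom = 3 * Q**2 / (20 * math.pi * prof.R)
        assert es.coulomb_energy(prof) == pytest.approx(U_hom, rel=1e-3)

    def test_large_X_quadrature_approaches_shell(self):
        prof = es.ChargeProfile("linearized", 1.0, 1000.0, 1.0, 1.0)
        Q = prof.total_charge()
        assert es.coulomb_energy_numeric(prof, 400_000) == pytest.approx(
            Q**2 / (8 * math.pi), rel=1e-3
        )

    def test_closed_form_matches_quadrature_at_moderate_X(self):
        prof = es.ChargeProfile("linearized", 1.0, 10.0, 1.0, 1.0)
        assert es.coulomb_energy(prof) == pytest.approx(
            es.coulomb_energy_numeric(prof, 400_000), rel=1e-6
        )

    def test_quadrature_richardson_convergence(self):
        prof = es.ChargeProfile("linearized", 1.0, 5.0, 1.0, 1.0)
        exact = es.coulomb_energy(prof)
        errs = [abs(es.coulomb_energy_numeric(prof, n) - exact) for n in (1000, 2000, 4000)]
        assert errs[1] < errs[0] and errs[2] < errs[1]


# ---------------------------------------------------------------------------
# Donnan potential
# ---------------------------------------------------------------------------

class TestDonnanPotential:
    def test_homogeneous_centre_potential(self):
        assert es.donnan_potential(es.homogeneous_profile(1.0, 1.0, 1.0)) == pytest.approx(0.5)

    def test_shell_centre_potential(self):
        assert es.donnan_potential(es.shell_profile(1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_closed_form_at_unit_X_and_quadrature(self):
        prof = es.ChargeProfile("linearized", 1.0, 1.0, 1.0, 1.0)
        phi = es.donnan_potential(prof)
        assert phi == pytest.approx(math.exp(-1), rel=1e-14)
        assert phi == pytest.approx(es.donnan_potential_numeric(prof), rel=1e-8)


# ---------------------------------------------------------------------------
# pressure
# ---------------------------------------------------------------------------

class TestCoulombPressure:
    def test_homogeneous_limit_value(self):
        assert es.coulomb_pressure(es.homogeneous_profile(1.0, 1.0, 1.0)) == pytest.approx(
            1 / 15, rel=1e-14
        )

    def test_shell_limit_value(self):
        assert es.coulomb_pressure(es.shell_profile(1.0, 1.0, 1.0)) == pytest.approx(0.5)

    def test_closed_form_matches_finite_difference(self):
        prof = es.ChargeProfile("linearized", 1.0, 10.0, 1.0, 1.0)
        p = es.coulomb_pressure(prof, check_printed=False)
        assert p == pytest.approx(es.pressure_numeric(prof, dR=1e-4), rel=1e-4)

    def test_finite_difference_second_order(self):
        prof = es.homogeneous_profile(1.0, 1.0, 1.0)
        exact = 1 / 15
        e1 = abs(es.pressure_numeric(prof, dR=2e-3) - exact)
        e2 = abs(es.pressure_numeric(prof, dR=1e-3) - exact)
        assert es.pressure_numeric(prof, dR=1e-4) == pytest.approx(exact, rel=1e-6)
        assert e1 / e2 >= 3.5

    def test_fixed_charge_shell_oracle(self):
        prof = es.shell_profile(1.0, 1.0, 1.0)
        assert es.pressure_numeric(prof, dR=1e-4) == pytest.approx(0.5, rel=1e-6)

    def test_transcribed_long_form_mismatch_is_flagged(self):
        prof = es.ChargeProfile("linearized", 1.0, 0.8, 1.0, 1.0)
        with pytest.warns(RuntimeWarning, match="transcription"):
            es.coulomb_pressure(prof, check_printed=True)

    def test_unsupported_kind_rejected(self):
        sol = es.solve_dimensionless_profile(2.0, -0.5, 64)
        grid = np.column_stack([sol.xs / 2.0, sol.ys])
        prof = es.ChargeProfile("numeric", -1.0, 2.0, 1.0, 1.0, grid=grid)
        with pytest.raises(ValueError):
            es.coulomb_pressure(prof)


# ---------------------------------------------------------------------------
# limits and scaling laws
# ---------------------------------------------------------------------------

class TestLimitsAndScaling:
    def test_pressure_small_X_convergence_rate(self):
        # p / (rho0^2 R^2 / 15 eps) = 1 - X/2 + O(X^2)
        for X in (1e-3, 1e-2, 1e-1):
            prof = es.ChargeProfile("linearized", 1.0, X, 1.0, 1.0)
            ratio = es.coulomb_pressure(prof, False) / (1 / 15)
            assert ratio - 1 == pytest.approx(-X / 2, rel=0.05)

    def test_pressure_large_X_convergence_rate(self):
        # p / (sigma^2 / 2 eps) = 1 - 3/X + O(1/X^2)
        for X in (1e2, 1e3, 4e3):
            prof = es.ChargeProfile("linearized", X, X, 1.0, 1.0)  # sigma = 1
            ratio = es.coulomb_pressure(prof, False) / 0.5
            assert ratio - 1 == pytest.approx(-3 / X, rel=0.05)

    def test_donnan_limit_convergence_rates(self):
        phi_small = es.donnan_potential(es.ChargeProfile("linearized", 1.0, 1e-3, 1.0, 1.0))
        assert phi_small == pytest.approx(0.5, rel=1e-3)
        phi_large = es.donnan_potential(es.ChargeProfile("linearized", 4e3, 4e3, 1.0, 1.0))
        assert phi_large / 1.0 - 1 == pytest.approx(-1 / 4e3, rel=0.01)

    def test_series_direct_crossover_continuity(self):
        # evaluation strategy switches at X=0.5; both sides must agree
        for X in (0.499999, 0.500001):
            prof = es.ChargeProfile("linearized", 1.0, X, 1.0, 1.0)
            p = es.coulomb_pressure(prof, False)
            assert p == pytest.approx(es.pressure_numeric(prof, dR=1e-5), rel=1e-6)

    def test_energy_and_pressure_scaling_laws(self, rng):
        for _ in range(5):
            X = float(rng.uniform(0.2, 20))
            rho0 = float(rng.uniform(0.1, 5))
            R = float(rng.uniform(0.5, 2))
            eps = float(rng.uniform(0.5, 2))
            base = es.ChargeProfile("linearized", rho0, X / R, R, eps)
            doubled = es.ChargeProfile("linearized", 2 * rho0, X / R, R, eps)
            half_eps = es.ChargeProfile("linearized", rho0, X / R, R, eps / 2)
            assert es.coulomb_energy(doubled) == pytest.approx(4 * es.coulomb_energy(base), rel=1e-12)
            assert es.coulomb_pressure(doubled, False) == pytest.approx(
                4 * es.coulomb_pressure(base, False), rel=1e-12
            )
            assert es.coulomb_energy(half_eps) == pytest.approx(
                2 * es.coulomb_energy(base), rel=1e-12
            )
            assert es.coulomb_pressure(half_eps, False) == pytest.approx(
                2 * es.coulomb_pressure(base, False), rel=1e-12
            )

    def test_oracle_equivalence_randomized(self, rng):
        for _ in range(20):
            X = float(np.exp(rng.uniform(np.log(0.05), np.log(50))))
            rho0 = float(rng.uniform(0.1, 10))
            R = float(rng.uniform(0.5, 2))
            eps = float(rng.uniform(0.5, 2))
            prof = es.ChargeProfile("linearized", rho0, X / R, R, eps)
            U = es.coulomb_energy(prof)
            p = es.coulomb_pressure(prof, check_printed=False)
            assert U == pytest.approx(es.coulomb_energy_numeric(prof, 100_000), rel=1e-3)
            assert p == pytest.approx(es.pressure_numeric(prof, dR=1e-5 * R), rel=1e-3)
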