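"""Oscillating-sphere viscoelastic response model and its inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import root

from pfoce.mechanics import (
    BeadSpec,
    ComplexResponse,
    MediumSpec,
    integrate_bead_eom,
    invert_geff,
    modulus_from_response,
    oestreicher_geff,
)

OMEGA = 2 * np.pi * 20.0
RADIUS = 0.95e-6
RHO = 1000.0


def massless_bead():
    # vanishing density isolates the quasi-static force balance
    return BeadSpec(diameter=1.9e-6, density=1e-12, refractive_index=1.68)


class TestOestreicherForward:
    def test_zero_density_is_identity(self):
        assert oestreicher_geff(100.0, OMEGA, RADIUS, 0.0) == pytest.approx(100.0)

    def test_small_ka_deviation_matches_direct_evaluation(self):
        g = 100 + 40j
        ka = OMEGA * np.sqrt(RHO / g) * RADIUS
        expected = g * (1 - 1j * ka - ka**2 / 9)
        out = oestreicher_geff(g, OMEGA, RADIUS, RHO)
        assert out == pytest.approx(expected)
        assert abs(out - g) / abs(g) < 2e-3  # |ka| ~ 4e-4 regime

    def test_point_sphere_limit(self):
        g = 80 + 10j
        out = oestreicher_geff(g, OMEGA, 1e-12, RHO)
        assert abs(out - g) / abs(g) < 1e-9

    def test_zero_modulus_rejected(self):
        with pytest.raises(ValueError):
            oestreicher_geff(0.0, OMEGA, RADIUS, RHO)

    def test_deviation_monotone_in_radius(self):
        g = 200 + 50j
        radii = np.linspace(0.2e-6, 5e-6, 20)
        dev = [abs(oestreicher_geff(g, OMEGA, r, RHO) - g) for r in radii]
        assert np.all(np.diff(dev) > 0)


class TestInversion:
    def test_round_trip_reference_point(self):
        g = 50 + 20j
        g_eff = oestreicher_geff(g, OMEGA, RADIUS, RHO)
        rec = invert_geff(g_eff, OMEGA, RADIUS, RHO, tol=1e-15)
        assert abs(rec - g) / abs(g) < 1e-9

    def test_zero_density_returns_input(self):
        assert invert_geff(123 + 4j, OMEGA, RADIUS, 0.0) == 123 + 4j

    @pytest.mark.parametrize("g_prime", [10.0, 100.0, 2000.0])
    @pytest.mark.parametrize("g_loss", [1.0, 50.0, 500.0])
    def test_agrees_with_newton_oracle(self, g_prime, g_loss):
        """Fixed-point inversion vs damped Newton on the complex residual."""
        g_true = g_prime + 1j * g_loss
        g_eff = oestreicher_geff(g_true, OMEGA, RADIUS, RHO)

        def residual(xy):
            g = xy[0] + 1j * xy[1]
            r = oestreicher_geff(g, OMEGA, RADIUS, RHO) - g_eff
            return [r.real, r.imag]

        sol = root(residual, [g_eff.real, g_eff.imag], tol=1e-14)
        assert sol.success
        oracle = sol.x[0] + 1j * sol.x[1]
        ours = invert_geff(g_eff, OMEGA, RADIUS, RHO, tol=1e-15)
        assert abs(ours - oracle) / abs(oracle) < 1e-8

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        g_prime=st.floats(10.0, 2000.0),
        g_loss=st.floats(1.0, 500.0),
    )
    def test_inversion_round_trip_property(self, g_prime, g_loss):
        g = g_prime + 1j * g_loss
        rec = invert_geff(oestreicher_geff(g, OMEGA, RADIUS, RHO), OMEGA, RADIUS, RHO)
        assert abs(rec - g) / abs(g) < 1e-8


class TestModulusFromResponse:
    def test_inertia_free_elastic_reference(self):
        """3 pN with a 304 pm in-phase response is a ~551 Pa elastic medium."""
        resp = ComplexResponse(amplitude=4 * 76e-12, phase_shift=0.0, angular_frequency=OMEGA)
        g = modulus_from_response(3e-12, resp, massless_bead(), medium_rho=0.0)
        assert g.real == pytest.approx(551.09, rel=1e-3)
        assert g.imag == pytest.approx(0.0, abs=1e-9)

    def test_forward_inverse_round_trip(self, bead):
        g_true = 200 + 60j
        g_eff = oestreicher_geff(g_true, OMEGA, bead.radius, RHO)
        d = 3e-12 / (6 * np.pi * bead.radius * g_eff - bead.mass * OMEGA**2)
        resp = ComplexResponse(
            amplitude=abs(d), phase_shift=float(np.angle(d)), angular_frequency=OMEGA
        )
        rec = modulus_from_response(3e-12, resp, bead, medium_rho=RHO, tol=1e-15)
        assert abs(rec - g_true) / abs(g_true) < 1e-9

    def test_quadrature_response_is_purely_viscous(self):
        resp = ComplexResponse(
            amplitude=1e-10, phase_shift=-np.pi / 2, angular_frequency=OMEGA
        )
        g = modulus_from_response(3e-12, resp, massless_bead(), medium_rho=0.0)
        assert abs(g.real) < 1e-9 * abs(g.imag)
        assert g.imag > 0

    def test_stokes_drag_limit(self):
        """Purely viscous medium G* = i omega eta reproduces F = 6 pi eta a v."""
        eta = 1.31e-3
        g_visc = 1j * OMEGA * eta
        amp = 1e-9
        force = abs(6 * np.pi * RADIUS * g_visc * amp)
        resp = ComplexResponse(amplitude=amp, phase_shift=-np.pi / 2, angular_frequency=OMEGA)
        bead = BeadSpec(diameter=2 * RADIUS, density=1e-12, refractive_index=1.6)
        g = modulus_from_response(force, resp, bead, medium_rho=0.0)
        v = OMEGA * amp  # |velocity| of the oscillation
        assert force == pytest.approx(6 * np.pi * eta * RADIUS * v, rel=1e-12)
        assert g.imag == pytest.approx(OMEGA * eta, rel=1e-9)

    def test_zero_amplitude_is_an_error(self):
        with pytest.raises(ValueError, match="amplitude"):
            ComplexResponse(amplitude=1e-12, phase_shift=0.0, angular_frequency=OMEGA)
            modulus_from_response(
                3e-12,
                ComplexResponse(amplitude=0.0, phase_shift=0.0, angular_frequency=OMEGA),
                massless_bead(),
            )


class TestBeadEquationOfMotion:
    def test_no_force_stays_put(self, bead):
        fluid = MediumSpec(refractive_index=1.33, density=1000.0, viscosity=1e-3)
        t, z, v = integrate_bead_eom(
            lambda z: 0.0, bead, fluid, z0=1e-6, duration=1e-3, dt=1e-4, gravity=False
        )
        assert np.allclose(z, 1e-6, atol=1e-15)

    def test_constant_force_matches_closed_form(self, bead):
        """Exponential approach to terminal velocity F/(6 pi eta a)."""
        fluid = MediumSpec(refractive_index=1.33, density=1000.0, viscosity=1.31e-3)
        F = 2e-12
        drag = 6 * np.pi * fluid.viscosity * bead.radius
        tau = bead.mass / drag
        v_term = F / drag
        t, z, v = integrate_bead_eom(
            lambda z: F, bead, fluid, z0=0.0, duration=20 * tau, dt=tau / 4, gravity=False
        )
        v_exact = v_term * (1 - np.exp(-t / tau))
        assert np.allclose(v[1:], v_exact[1:], rtol=1e-6)

    def test_terminal_velocity_reached(self, bead):
        fluid = MediumSpec(refractive_index=1.33, density=1000.0, viscosity=1.31e-3)
        F = 3e-12
        drag = 6 * np.pi * fluid.viscosity * bead.radius
        t, z, v = integrate_bead_eom(
            lambda z: F, bead, fluid, z0=0.0, duration=0.1, dt=0.01, gravity=False
        )
        assert v[-1] == pytest.approx(F / drag, rel=1e-6)

    def test_neutral_buoyancy_stationary(self, bead):
        fluid = MediumSpec(refractive_index=1.33, density=bead.density, viscosity=1e-3)
        t, z, v = integrate_bead_eom(
            lambda z: 0.0, bead, fluid, z0=5e-6, duration=0.05, dt=0.01, gravity=True
        )
        assert np.allclose(z, 5e-6, atol=1e-14)

    def test_non_finite_force_rejected(self, bead):
        fluid = MediumSpec(refractive_index=1.33, density=1000.0, viscosity=1e-3)
        with pytest.raises((ValueError, RuntimeError)):
            integrate_bead_eom(
                lambda z: np.nan, bead, fluid, z0=0.0, duration=0.01, dt=0.001
            )
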