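"""Light-sheet optics, Mie/GLMT radiation force, and acquisition arithmetic."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.spatial import cKDTree

from pfoce import mie
from pfoce.beam import (
    AcquisitionPlan,
    LightSheetBeam,
    acquisition_times,
    bead_volume_fraction,
    displacement_sensitivity,
    force_profile_from_model,
    glmt_force,
    lightsheet_intensity,
    max_measurable_modulus,
)
from pfoce.mechanics import BeadSpec


class TestMie:
    def test_reference_efficiencies(self):
        """Classic benchmark: m = 1.5, x = 10 has Q_ext = 2.8820."""
        q_ext, q_sca, _ = mie.mie_efficiencies(1.5, 10.0)
        assert q_ext == pytest.approx(2.8820, abs=2e-4)
        assert q_sca == pytest.approx(q_ext, rel=1e-12)  # non-absorbing

    def test_rayleigh_scattering_limit(self):
        m, x = 1.263, 0.05
        _, q_sca, _ = mie.mie_efficiencies(m, x)
        rayleigh = 8.0 / 3.0 * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2
        assert q_sca == pytest.approx(rayleigh, rel=5e-4)

    def test_glmt_series_reduces_to_plane_wave(self):
        m, x = 1.263, 10.06
        k = 2 * np.pi * 1.33 / 789e-9
        q_ext, _, g_q_sca = mie.mie_efficiencies(m, x)
        c_pr_pw = mie.pressure_cross_section(m, x, k)  # no beam waists
        area = np.pi * (x / k) ** 2
        assert c_pr_pw / area == pytest.approx(q_ext - g_q_sca, rel=1e-10)

    def test_sheet_bsc_below_unity_and_circular_limit(self):
        k = 2 * np.pi * 1.33 / 789e-9
        n = np.arange(1, 20)
        g = mie.localized_sheet_bsc(n, k, 1.19e-6, 67.9e-6)
        assert np.all(g <= 1.0) and np.all(np.diff(g) < 0)
        g_circ = mie.localized_sheet_bsc(n, k, 5e-6, 5e-6)
        rho2 = ((n + 0.5) / k) ** 2
        assert np.allclose(g_circ, np.exp(-rho2 / 5e-6**2), rtol=1e-10)


class TestIntensity:
    def test_peak_is_gaussian_normalisation(self, beam):
        wx, wy = beam.waist_long, beam.waist_short
        peak = lightsheet_intensity(beam, 0.0, 0.0, 0.0)
        assert peak == pytest.approx(2 * beam.power / (np.pi * wx * wy), rel=1e-12)

    def test_half_maximum_contour_at_stated_fwhms(self, beam):
        peak = lightsheet_intensity(beam, 0.0, 0.0, 0.0)
        assert lightsheet_intensity(beam, 40e-6, 0.0, 0.0) == pytest.approx(peak / 2, rel=1e-9)
        assert lightsheet_intensity(beam, 0.0, 0.7e-6, 0.0) == pytest.approx(peak / 2, rel=1e-9)

    @pytest.mark.parametrize("z", [0.0, 40e-6])
    def test_plane_integral_equals_power(self, beam, z):
        wx, wy = beam.spot_sizes(z, 1.33)
        x = np.linspace(-6 * wx, 6 * wx, 801)
        y = np.linspace(-6 * wy, 6 * wy, 801)
        intensity = lightsheet_intensity(beam, x[:, None], y[None, :], z)
        integral = np.trapezoid(np.trapezoid(intensity, y, axis=1), x)
        assert integral == pytest.approx(beam.power, rel=1e-6)


class TestGlmtForce:
    def test_zero_power_zero_force(self, bead, water):
        dark = LightSheetBeam(power=1e-300)
        assert glmt_force(dark, bead, water)[2] == pytest.approx(0.0, abs=1e-20)

    def test_peak_force_near_three_piconewtons(self, beam, bead, water):
        f = glmt_force(beam, bead, water)[2]
        assert 3e-12 * 0.75 < f < 3e-12 * 1.25

    def test_linear_in_power(self, beam, bead, water):
        double = replace(beam, power=2 * beam.power)
        assert glmt_force(double, bead, water)[2] == pytest.approx(
            2 * glmt_force(beam, bead, water)[2], rel=1e-12
        )

    def test_rayleigh_limit_matches_dipole_oracle(self, beam, water):
        """50-nm bead: GLMT force ~ dipole scattering force n I C_sca / c."""
        tiny = BeadSpec(diameter=50e-9, density=1510, refractive_index=1.68)
        f = glmt_force(beam, tiny, water)[2]
        m = tiny.refractive_index / water.refractive_index
        k = 2 * np.pi * water.refractive_index / beam.wavelength
        x = k * tiny.radius
        q_pr = 8.0 / 3.0 * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2
        intensity = lightsheet_intensity(beam, 0, 0, 0, water.refractive_index)
        dipole = water.refractive_index / 299792458.0 * intensity * q_pr * np.pi * tiny.radius**2
        assert f == pytest.approx(dipole, rel=0.05)


class TestForceProfile:
    def test_lateral_fwhm_tracks_intensity(self, model_force_map, beam):
        row = model_force_map.force[np.argmin(np.abs(model_force_map.grid_z))]
        x = model_force_map.grid_x
        half = row.max() / 2
        above = x[row >= half]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(beam.fwhm_long, rel=0.04)  # grid-limited

    def test_profile_symmetric_in_x(self, model_force_map):
        f = model_force_map.force
        assert np.allclose(f, f[:, ::-1], rtol=1e-10)

    def test_doubling_power_doubles_profile(self, beam, bead, gel_medium):
        grid_x = np.linspace(-20e-6, 20e-6, 5)
        grid_z = np.array([0.0, 10e-6])
        base = force_profile_from_model(beam, bead, gel_medium, grid_x, grid_z)
        double = force_profile_from_model(
            replace(beam, power=2 * beam.power), bead, gel_medium, grid_x, grid_z
        )
        assert np.allclose(double.force, 2 * base.force, rtol=1e-12)


class TestSensitivityAndPlanning:
    def test_shot_noise_sensitivity_reference(self, plan):
        assert displacement_sensitivity(plan) == pytest.approx(27e-12, rel=0.01)

    def test_inverse_sqrt_frames_scaling(self, plan):
        quad = replace(plan, n_frames=4 * plan.n_frames)
        assert displacement_sensitivity(quad) == pytest.approx(
            displacement_sensitivity(plan) / 2, rel=1e-12
        )

    def test_max_modulus_endpoints(self):
        low = max_measurable_modulus(3e-12, 0.95e-6, 76e-12)
        high = max_measurable_modulus(3e-12, 0.95e-6, 36e-12)
        assert low == pytest.approx(551.0, rel=0.01)
        assert high == pytest.approx(1163.0, rel=0.01)
        assert max_measurable_modulus(3e-12, 0.95e-6, 2 * 76e-12) == pytest.approx(
            low / 2, rel=1e-12
        )

    def test_acquisition_times_reference(self, plan):
        per, n_pos, total, total_wait = acquisition_times(plan)
        assert per == pytest.approx(15.06, abs=0.01)
        assert n_pos == 467
        assert total / 60 == pytest.approx(117.2, abs=0.3)
        assert total_wait == pytest.approx(total + 6.0 * n_pos, rel=1e-12)

    def test_single_position_scan(self, plan):
        static = replace(plan, slow_range=0.0)
        per, n_pos, total, _ = acquisition_times(static)
        assert n_pos == 1 and total == per

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionPlan(slow_range=10e-6, slow_step=0.0)


class TestVolumeFraction:
    def test_live_cell_operating_point_below_bound(self):
        phi = bead_volume_fraction(1.9e-6, 20e-6)
        assert phi == pytest.approx(5.8e-5, rel=0.02)
        assert phi < 1e-4

    def test_vanishes_at_large_spacing(self):
        assert bead_volume_fraction(1.9e-6, 1.0) < 1e-15

    def test_poisson_nearest_neighbour_oracle(self):
        """Direct Poisson placement reproduces the 0.554 n^(-1/3) relation."""
        diameter, spacing = 1.9e-6, 20e-6
        phi = bead_volume_fraction(diameter, spacing)
        density = phi / (np.pi / 6 * diameter**3)
        rng = np.random.default_rng(0)
        box = 400e-6
        n_pts = rng.poisson(density * box**3)
        pts = rng.uniform(0, box, size=(n_pts, 3))
        tree = cKDTree(pts, boxsize=box)  # periodic wrap avoids edge bias
        dist, _ = tree.query(pts, k=2)
        mean_nn = dist[:, 1].mean()
        assert mean_nn == pytest.approx(spacing + diameter, rel=0.03)
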