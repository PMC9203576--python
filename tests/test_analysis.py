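"""Pericellular gradients, deformation tracking, shell metrics, statistics."""

import numpy as np
import pytest
from scipy import stats

from pfoce.analysis import (
    confocal_postprocess,
    correlate_metrics,
    cumulative_displacement,
    distance_profile,
    distance_to_cell,
    distribution_fwhm,
    fit_power_law,
    group_by_deformation,
    group_tests,
    shell_metrics,
    signed_displacement,
    speckle_segment_cell,
)
from pfoce.synthetic import gen_pericellular_scene


class TestSpeckleSegmentation:
    def test_static_volume_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        static = np.sqrt(rng.exponential(size=(20, 20, 20)))
        movie = np.tile(static, (8, 1, 1, 1))
        with pytest.warns(UserWarning, match="empty"):
            mask = speckle_segment_cell(movie, contrast_threshold=0.1)
        assert not mask.any()

    def test_all_dynamic_volume_warns_degenerate(self):
        rng = np.random.default_rng(1)
        movie = np.sqrt(rng.exponential(size=(8, 12, 12, 12)))
        with pytest.warns(UserWarning, match="dynamic"):
            mask = speckle_segment_cell(movie, contrast_threshold=0.0)
        assert mask.all()

    def test_planted_ellipsoid_dice_over_090(self):
        scene = gen_pericellular_scene(
            n_beads=10, with_speckle_movie=True, n_frames=16, seed=3
        )
        mask = speckle_segment_cell(scene["movie"])
        truth = scene["cell_mask"]
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.9


class TestDistanceToCell:
    def test_bead_inside_mask_distance_zero(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 4:6, 4:6] = True
        r = distance_to_cell(np.array([[4.5e-6, 4.5e-6, 4.5e-6]]), mask, [1e-6] * 3)
        assert r[0] == 0.0

    def test_spherical_mask_analytic_distance(self):
        pixel = 1e-6
        shape = (60, 60, 60)
        centre = np.array([30.0, 30.0, 30.0]) * pixel
        grids = np.meshgrid(*[np.arange(s) * pixel for s in shape], indexing="ij")
        mask = sum((g - c) ** 2 for g, c in zip(grids, centre)) <= (10e-6) ** 2
        bead = centre + np.array([25e-6, 0, 0])
        r = distance_to_cell(bead[None, :], mask, [pixel] * 3)
        assert r[0] == pytest.approx(15e-6, abs=pixel * np.sqrt(3))

    def test_distance_scales_with_pixel_size(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[10, 10, 10] = True
        bead = np.array([[5.0, 10.0, 10.0]])
        r1 = distance_to_cell(bead * 1e-6, mask, [1e-6] * 3)
        r2 = distance_to_cell(bead * 2e-6, mask, [2e-6] * 3)
        assert r2[0] == pytest.approx(2 * r1[0], rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            distance_to_cell(np.zeros((1, 3)), np.zeros((5, 5, 5), bool), [1e-6] * 3)


class TestDistanceProfile:
    def test_identical_beads_zero_ci(self):
        r = np.array([1e-6, 2e-6, 4e-6, 5e-6, 7e-6])
        g = np.full(5, 100.0)
        prof = distance_profile(g, g * 0.2, r)
        filled = np.isfinite(prof.g_prime_mean)
        assert np.allclose(prof.g_prime_mean[filled], 100.0)
        ci = prof.g_prime_ci[filled & (prof.n >= 2)]
        assert np.allclose(ci, 0.0)

    def test_t_interval_reference_n5(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100.0, 10.0, 5)
        r = np.full(5, 1e-6)
        prof = distance_profile(vals, vals, r)
        s = vals.std(ddof=1)
        expected = 2.776 * s / np.sqrt(5)
        assert prof.g_prime_ci[0] == pytest.approx(expected, rel=1e-3)

    def test_background_normalises_to_unity(self):
        rng = np.random.default_rng(1)
        r = np.concatenate([rng.uniform(0, 25e-6, 40), rng.uniform(32e-6, 60e-6, 40)])
        g = np.concatenate([rng.uniform(150, 250, 40), np.full(40, 80.0)])
        prof = distance_profile(g, g, r, normalise=True)
        bg_bins = prof.r >= 32e-6
        means = prof.g_prime_mean[bg_bins]
        assert np.allclose(means[np.isfinite(means)], 1.0, rtol=1e-9)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        r = np.linspace(2e-6, 28e-6, 40)
        g = 300.0 * (r / 30e-6) ** -0.19
        beta, ci = fit_power_law(r, g)
        assert beta == pytest.approx(-0.19, abs=1e-12)
        assert ci == pytest.approx(0.0, abs=1e-10)

    def test_constant_profile_zero_exponent(self):
        r = np.linspace(1e-6, 25e-6, 20)
        beta, _ = fit_power_law(r, np.full(20, 123.0))
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1e-6, 2e-6, 3e-6]), np.array([1.0, -2.0, 3.0]))

    def test_ci_covers_generating_exponent(self):
        """Coverage of the 95% CI on the synthetic pericellular scene."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            scene = gen_pericellular_scene(beta=-0.19, n_beads=120, seed=seed)
            sel = (scene["r"] > 0) & (scene["r"] <= 30e-6)
            beta, ci = fit_power_law(scene["r"][sel], scene["g_prime"][sel])
            if abs(beta - (-0.19)) <= ci:
                hits += 1
        assert hits / n_rep >= 0.88  # ~95% nominal, small-sample slack


class TestDisplacementStatistics:
    def test_common_translation_cancels_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 50e-6, size=(1, 12, 3))
        shifts = np.cumsum(rng.normal(0, 1e-6, size=(6, 1, 3)), axis=0)
        pos = np.repeat(base, 6, axis=0) + shifts
        delta = cumulative_displacement(pos)
        assert np.allclose(delta, 0.0, atol=1e-18)

    def test_two_beads_equal_and_opposite(self):
        """+/- u per step accumulates to +/- (n-1) u after bulk correction."""
        u = 0.5e-6
        n_t = 5
        pos = np.zeros((n_t, 2, 3))
        for i in range(n_t):
            pos[i, 0, 0] = +u * i
            pos[i, 1, 0] = -u * i
        delta = cumulative_displacement(pos)
        for n in range(n_t):
            assert delta[n, 0, 0] == pytest.approx(+n * u)
            assert delta[n, 1, 0] == pytest.approx(-n * u)

    def test_static_beads_zero(self):
        pos = np.tile(np.random.default_rng(1).uniform(0, 1e-5, (1, 8, 3)), (4, 1, 1))
        assert np.allclose(cumulative_displacement(pos), 0.0)

    def test_signed_displacement_single_axis(self):
        delta = np.zeros((3, 1, 3))
        delta[:, 0, 0] = [0.0, 1e-6, 2e-6]
        s, major = signed_displacement(delta)
        assert major == 0
        assert np.allclose(s[:, 0], [0.0, 1e-6, 2e-6])

    def test_mirror_antisymmetry(self):
        rng = np.random.default_rng(2)
        delta = rng.normal(0, 1e-6, size=(4, 6, 3))
        delta[:, :, 0] *= 3.0  # make x clearly the major axis
        s1, m1 = signed_displacement(delta)
        mirrored = delta.copy()
        mirrored[:, :, 0] *= -1
        s2, m2 = signed_displacement(mirrored)
        assert m1 == m2 == 0
        np.testing.assert_allclose(s2, -s1)

    def test_major_axis_is_dataset_level(self):
        """Beads follow the dataset-dominant axis even when their own largest
        component is another axis."""
        delta = np.zeros((2, 4, 3))
        # three beads dominated by y, one by x
        delta[1, 0] = [0.1e-6, 1.0e-6, 0.0]
        delta[1, 1] = [0.2e-6, 2.0e-6, 0.0]
        delta[1, 2] = [0.0, -1.5e-6, 0.1e-6]
        delta[1, 3] = [1.0e-6, 0.4e-6, 0.0]  # x-dominant bead
        s, major = signed_displacement(delta)
        assert major == 1
        assert s[1, 3] == pytest.approx(np.sign(0.4e-6) * np.linalg.norm(delta[1, 3]))

    def test_grouping_by_signed_threshold(self):
        labels = group_by_deformation(np.array([-5e-6, -0.1e-6, 4e-6]), s_hi=1e-6)
        assert list(labels) == ["high-negative", "low", "high-positive"]
        assert list(group_by_deformation(np.zeros(3))) == ["low"] * 3

    def test_percentile_threshold_tercile_like(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(-1, 1, 3000)
        labels = group_by_deformation(s)
        frac_high = np.mean(labels != "low")
        assert frac_high == pytest.approx(0.33, abs=0.03)


class TestShellMetrics:
    def make_shell_volume(self, shell_value=5.0, n=40, pixel=0.5e-6):
        vol = np.full((n, n, n), shell_value)
        centre = np.array([n / 2, n / 2, n / 2]) * pixel
        return vol, centre, pixel

    def test_uniform_shell_q95_equals_mean(self):
        vol, centre, pixel = self.make_shell_volume(5.0)
        out = shell_metrics(vol, centre[None, :], 0.95e-6, [pixel] * 3,
                            noise_power=1.0)
        m = out[0]
        assert m.q95_intensity == pytest.approx(5.0)
        assert m.mean_intensity == pytest.approx(5.0)
        assert m.fibre_volume_fraction in (0.0, 1.0)

    def test_planted_fraction_recovered(self):
        """30% of shell voxels above the fibre threshold, all above noise."""
        rng = np.random.default_rng(0)
        vol, centre, pixel = self.make_shell_volume(10 ** (8 / 20))  # 8 dB amplitude
        fibre_amp = 10 ** (16 / 20)
        grids = np.meshgrid(*[np.arange(40) * pixel for _ in range(3)], indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        shell = (d2 <= (0.95e-6 + 3e-6) ** 2) & (d2 > (0.95e-6) ** 2)
        idx = np.flatnonzero(shell)
        chosen = rng.choice(idx, size=int(round(0.3 * len(idx))), replace=False)
        vol.ravel()[chosen] = fibre_amp
        out = shell_metrics(vol, centre[None, :], 0.95e-6, [pixel] * 3,
                            noise_power=1.0, removal_dilation=0)
        assert out[0].fibre_volume_fraction == pytest.approx(0.30, abs=0.02)

    def test_zero_shell_flagged(self):
        vol, centre, pixel = self.make_shell_volume()
        with pytest.raises(ValueError):
            shell_metrics(vol, centre[None, :], 0.95e-6, [pixel] * 3,
                          noise_power=1.0, shell=0.0)

    def test_fraction_invariant_to_global_rescale(self):
        rng = np.random.default_rng(1)
        vol, centre, pixel = self.make_shell_volume(2.0)
        vol += rng.uniform(0, 10, vol.shape)
        out1 = shell_metrics(vol, centre[None, :], 0.95e-6, [pixel] * 3,
                             noise_power=1.0)
        out2 = shell_metrics(vol * 10, centre[None, :], 0.95e-6, [pixel] * 3,
                             noise_power=100.0)
        assert out1[0].fibre_volume_fraction == pytest.approx(
            out2[0].fibre_volume_fraction
        )


class TestCorrelationsAndTests:
    def test_monotone_pairs_unit_rho(self):
        x = np.arange(10.0)
        rho, _ = correlate_metrics(x, x**3 + 1)
        assert rho == pytest.approx(1.0, abs=1e-12)
        rho, _ = correlate_metrics(x, -x)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_metrics(np.ones(6), np.arange(6.0))

    def test_exact_permutation_p_at_n8(self):
        """Exact enumeration of rank permutations as the p-value oracle."""
        from itertools import permutations

        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = 0.6 * x + rng.normal(size=8) * 0.8
        rho, p = correlate_metrics(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(stats.pearsonr(rx, ry).statistic)
        count = sum(
            abs(stats.pearsonr(rx, np.array(perm)).statistic) >= obs - 1e-12
            for perm in permutations(ry)
        )
        assert p == pytest.approx(count / 40320, abs=0.01)

    def test_welch_reference_statistic(self):
        out = group_tests(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert out["welch_t"] == pytest.approx(-3.674, abs=1e-3)
        assert out["mean_difference"] == -3.0

    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2, 3, 4])
        out = group_tests(a, a.copy())
        assert out["welch_p"] == pytest.approx(1.0)

    def test_levene_type_one_error_rate(self):
        """Equal-variance groups are rejected at roughly the nominal 5%."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(0, 1, 25)
            b = rng.normal(1, 1, 25)
            if group_tests(a, b)["levene_p"] < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestDistributionFwhm:
    def test_gaussian_reference_width(self):
        samples = np.random.default_rng(0).normal(5.0, 2.0, 4000)
        assert distribution_fwhm(samples) == pytest.approx(2.3548 * 2.0, rel=0.05)

    def test_scaling_property(self):
        samples = np.random.default_rng(1).normal(0, 1.0, 2000)
        f1 = distribution_fwhm(samples)
        f2 = distribution_fwhm(3.0 * samples)
        assert f2 == pytest.approx(3 * f1, rel=0.02)

    def test_degenerate_sample_zero(self):
        assert distribution_fwhm(np.full(50, 2.5)) == 0.0


class TestConfocalPostprocess:
    def test_percentile_threshold_retains_top_fifth(self):
        img = np.arange(1.0, 101.0).reshape(10, 10)
        out = confocal_postprocess(img)
        thr = np.percentile(img, 80)
        assert thr == pytest.approx(80.2)
        assert (out > 0).sum() == (img >= thr).sum()

    def test_gamma_one_is_monotone_scaling(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (20, 20))
        out = confocal_postprocess(img, gamma=1.0)
        kept = img >= np.percentile(img, 80)
        np.testing.assert_allclose(out[kept], img[kept] / img.max())

    def test_constant_image_all_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            out = confocal_postprocess(np.full((5, 5), 3.0))
        assert not out.any()
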