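"""Spectral decomposition oracles: curvature, frequency recovery, binning,
and calibration/sensitivity of the cluster-corrected F-test."""

import numpy as np
import pytest

from animakin import (
    DegenerateTrajectoryError,
    SpectralBins,
    TrajectoryRecipe,
    WordCategory,
    afsd_spectrum,
    bin_areas,
    cluster_ftest,
    combine_triangles,
    curvature_and_frenet_speed,
    default_grid,
    gen_null_spectra,
    gen_pure_frequency_trajectory,
    spectral_profile,
)

from conftest import circle_xy


def delta_like_density(center, width=0.02):
    """Unit-area density concentrated in a narrow triangle around center."""
    grid = default_grid()
    d = np.clip(1 - np.abs(grid - center) / width, 0, None)
    return d / np.trapezoid(d, grid)


class TestCurvature:
    def test_circle_has_constant_curvature_and_log_speed(self):
        radius = 300.0
        xy = circle_xy(4000, radius, cycles=3.0)
        theta, log_v, weight = curvature_and_frenet_speed(xy)
        # curvature = dphi/ds = 1/R; log speed constant on a uniform circle
        v = np.exp(log_v)
        dtheta = np.diff(theta)
        ds = v[:-1]  # px per frame
        curvature = dtheta / ds
        assert np.allclose(curvature[20:-20], 1 / radius, rtol=0.01)
        assert np.std(log_v[20:-20]) < 1e-3
        assert weight > 0.95

    def test_straight_line_is_degenerate(self):
        n = 500
        xy = np.column_stack([np.linspace(10, 900, n), np.full(n, 50.0)])
        with pytest.raises(DegenerateTrajectoryError):
            curvature_and_frenet_speed(xy)

    def test_ellipse_speed_oscillates_twice_per_tracing(self):
        # constant-angular-rate parametrization of an ellipse: speed (and
        # curvature) complete exactly two oscillations per full tracing
        n = 8000
        ang = 2 * np.pi * 4.0 * np.arange(n) / n
        xy = np.column_stack([960 + 400 * np.cos(ang), 540 + 200 * np.sin(ang)])
        theta, log_v, _ = curvature_and_frenet_speed(xy)
        density, degen = afsd_spectrum(theta, log_v)
        assert not degen
        grid = default_grid()
        peak = grid[np.argmax(density)]
        assert abs(peak - 2.0) < 0.15


class TestSpectrum:
    def make_theta_logv(self, nu, amplitude=0.5, tracings=10, n=4000):
        theta = np.linspace(0, 2 * np.pi * tracings, n)
        return theta, amplitude * np.sin(nu * theta)

    def test_planted_two_peaks_in_ellipse_bin(self):
        theta, log_v = self.make_theta_logv(2.0)
        density, degen = afsd_spectrum(theta, log_v)
        grid = default_grid()
        peak = grid[np.argmax(density)]
        assert not degen and 1.61 <= peak <= 2.39

    def test_planted_five_peaks_in_pentagon_bin(self):
        theta, log_v = self.make_theta_logv(5.0)
        density, _ = afsd_spectrum(theta, log_v)
        grid = default_grid()
        areas = bin_areas(density)
        assert 4.79 <= grid[np.argmax(density)] <= 5.19
        assert np.argmax(areas) == 5  # bin 6

    @pytest.mark.parametrize("nu", range(1, 10))
    def test_frequency_recovery_within_tolerance(self, nu):
        theta, log_v = self.make_theta_logv(float(nu), amplitude=0.3)
        density, _ = afsd_spectrum(theta, log_v)
        grid = default_grid()
        assert abs(grid[np.argmax(density)] - nu) <= 0.15

    def test_zero_signal_flagged_degenerate(self):
        theta = np.linspace(0, 20 * np.pi, 2000)
        density, degen = afsd_spectrum(theta, np.zeros_like(theta))
        assert degen
        assert np.trapezoid(density, default_grid()) == pytest.approx(1.0)

    def test_insufficient_rotation_raises(self):
        theta = np.linspace(0, np.pi, 200)  # half a tracing
        with pytest.raises(DegenerateTrajectoryError, match="2\\*pi"):
            afsd_spectrum(theta, np.sin(theta))

    def test_unit_area_normalization(self):
        theta, log_v = self.make_theta_logv(3.0)
        density, _ = afsd_spectrum(theta, log_v)
        assert np.trapezoid(density, default_grid()) == pytest.approx(1.0, abs=1e-9)

    def test_speed_scale_invariance(self):
        # multiplying speed by a constant adds a constant to log v, which
        # the polynomial detrend removes
        theta, log_v = self.make_theta_logv(4.0)
        d1, _ = afsd_spectrum(theta, log_v)
        d2, _ = afsd_spectrum(theta, log_v + np.log(7.3))
        assert np.allclose(d1, d2, atol=1e-8)


class TestCombineAndBins:
    def test_equal_weights_pointwise_average(self):
        a, b = delta_like_density(2.0), delta_like_density(5.0)
        c = combine_triangles(a, b, 0.5, 0.5)
        assert np.allclose(c, (a + b) / 2)

    def test_zero_weight_returns_other_density(self):
        a, b = delta_like_density(2.0), delta_like_density(5.0)
        assert np.allclose(combine_triangles(a, b, 1.0, 0.0), a)

    def test_weighted_three_to_one_mass_split(self):
        a, b = delta_like_density(2.0), delta_like_density(5.0)
        c = combine_triangles(a, b, 0.75, 0.25)
        areas = bin_areas(c)
        assert areas[1] == pytest.approx(3 * areas[5], rel=1e-6)

    def test_both_weights_zero_raises(self):
        a = delta_like_density(2.0)
        with pytest.raises(DegenerateTrajectoryError):
            combine_triangles(a, a, 0.0, 0.0)

    def test_delta_density_mass_lands_in_bin_2(self):
        areas = bin_areas(delta_like_density(2.0))
        assert areas[1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.delete(areas, 1) < 1e-9)

    def test_uniform_density_areas_proportional_to_width(self):
        grid = default_grid()
        uniform = np.full(grid.size, 1 / (grid[-1] - grid[0]))
        areas = bin_areas(uniform)
        widths = np.array([hi - lo for lo, hi in SpectralBins().edges])
        assert np.allclose(areas, widths / (grid[-1] - grid[0]), atol=1e-12)
        assert areas.sum() < 1.0  # bins do not tile the grid

    def test_bins_must_not_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            SpectralBins(edges=((0.5, 2.0), (1.5, 3.0)))


class TestGeneratorSpectrumEndToEnd:
    @pytest.mark.parametrize("nu", [1, 2, 5, 9])
    def test_pipeline_recovers_planted_frequency(self, nu):
        rec = gen_pure_frequency_trajectory(
            TrajectoryRecipe(components=((float(nu), 0.5, 0.0),), seed=nu)
        )
        prof = spectral_profile(rec)
        peak = prof.grid[np.argmax(prof.combined_density)]
        assert abs(peak - nu) <= 0.15

    def test_two_component_bin_area_ordering(self):
        rec = gen_pure_frequency_trajectory(
            TrajectoryRecipe(components=((2.0, 0.5, 0.0), (5.0, 0.25, 0.7)), seed=3)
        )
        prof = spectral_profile(rec)
        assert prof.bin_areas[1] > prof.bin_areas[5] > 0

    def test_zero_amplitude_recording_flagged_degenerate(self):
        rec = gen_pure_frequency_trajectory(
            TrajectoryRecipe(components=((2.0, 0.0, 0.0),), seed=0)
        )
        prof = spectral_profile(rec)
        assert prof.degenerate


class TestClusterFTest:
    def test_injected_band_detected(self):
        spectra, labels, grid = gen_null_spectra(20, 101, seed=1)
        bump = 2.0 * np.exp(-0.5 * ((grid - 5.0) / 0.15) ** 2)
        idx = [i for i, l in enumerate(labels) if l is WordCategory.SURPRISING]
        spectra[idx] += bump
        spectra /= np.trapezoid(spectra, grid, axis=1)[:, None]
        res = cluster_ftest(spectra, labels, n_boot=300, alpha=0.05, seed=2)
        sig = res.significant_clusters
        assert sig
        covers = any(
            grid[c["start_idx"]] <= 5.0 <= grid[c["end_idx"]] for c in sig
        )
        assert covers

    def test_fixed_seed_is_bit_reproducible(self):
        spectra, labels, _ = gen_null_spectra(5, 51, seed=4)
        r1 = cluster_ftest(spectra, labels, n_boot=100, seed=9)
        r2 = cluster_ftest(spectra, labels, n_boot=100, seed=9)
        assert np.array_equal(r1.pointwise_F, r2.pointwise_F)
        assert r1.clusters == r2.clusters

    def test_zero_boots_rejected(self):
        spectra, labels, _ = gen_null_spectra(3, 21, seed=0)
        with pytest.raises(ValueError, match="n_boot"):
            cluster_ftest(spectra, labels, n_boot=0)

    def test_single_group_rejected(self):
        spectra, _, _ = gen_null_spectra(3, 21, seed=0)
        with pytest.raises(ValueError, match="group"):
            cluster_ftest(spectra[:3], ["a"] * 3, n_boot=10)

    def test_null_rate_bounded(self):
        # 40 exchangeable datasets; familywise rate should be near alpha
        hits = 0
        n_sets = 40
        for s in range(n_sets):
            spectra, labels, _ = gen_null_spectra(10, 61, seed=100 + s)
            res = cluster_ftest(spectra, labels, n_boot=200, alpha=0.05,
                                seed=500 + s)
            hits += bool(res.significant_clusters)
        # binomial upper bound at p=0.05, n=40: mean 2, sd ~1.38
        assert hits <= 6
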