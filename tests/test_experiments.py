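"""Experiment drivers: tracking of analytic slopes, substream policy,
residual fingerprints."""

import numpy as np
import pytest

from slopebench import (
    CovarianceSpec,
    SharedErrorParams,
    TriadSample,
    default_rho_grid,
    residual_diagnostics,
    run_independent_sweep,
    run_loose_additivity_study,
    run_shared_error_study,
    run_subtractive_sweep,
    shared_error_expected_slopes,
)

SMALL_GRID = np.array([-0.8, -0.4, 0.0, 0.4, 0.8])


def test_default_grid_matches_figure_density():
    grid = default_rho_grid()
    assert grid[0] == -0.9 and grid[-1] == 0.9 and len(grid) == 19
    np.testing.assert_allclose(np.diff(grid), 0.1)


class TestSubtractiveSweep:
    def test_mean_slope_tracks_analytic_expectation(self, spec_ae):
        res = run_subtractive_sweep(
            spec_ae, rho_grid=SMALL_GRID, iterations=2000, seed=3
        )
        np.testing.assert_allclose(res.expected_slope, SMALL_GRID - 1.0)
        dev = np.abs(res.mean_slope - res.expected_slope)
        assert np.all(dev <= 5 * res.mc_se_slope)

    def test_rejection_monotone_in_distance_from_null(self, spec_ae):
        res = run_subtractive_sweep(
            spec_ae, rho_grid=SMALL_GRID, iterations=2000, seed=4
        )
        r = dict(zip(res.rho_grid, res.rejection_rate))
        assert r[0.0] < r[0.4] < r[0.8]
        assert r[0.0] < r[-0.4] < r[-0.8]

    def test_condition_results_independent_of_grid_order(self, spec_ae):
        full = run_subtractive_sweep(
            spec_ae, rho_grid=np.array([0.0, 0.5]), iterations=500, seed=7
        )
        single = run_subtractive_sweep(
            spec_ae, rho_grid=np.array([0.5]), iterations=500, seed=7
        )
        assert full.mean_slope[1] == single.mean_slope[0]
        assert full.rejection_rate[1] == single.rejection_rate[0]

    def test_invalid_grid_rejected(self, spec_ae):
        with pytest.raises(ValueError):
            run_subtractive_sweep(spec_ae, rho_grid=np.array([0.0, 1.0]))

    def test_dataframe_schema_is_stable(self, spec_ae):
        res = run_subtractive_sweep(
            spec_ae, rho_grid=np.array([0.0]), iterations=50, seed=0
        )
        assert list(res.to_dataframe().columns) == [
            "rho", "expected_slope", "mean_slope", "sd_slope", "mc_se_slope",
            "rejection_rate", "rejection_se", "n", "iterations", "benchmark",
            "alpha", "design",
        ]


class TestIndependentSweep:
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_mean_slope_tracks_rho_times_sd_ratio(self, ratio):
        spec = CovarianceSpec(0.0, 0.0, 2.5, 2.5, 0.0)
        res = run_independent_sweep(
            spec, rho_grid=SMALL_GRID, variance_ratio=ratio,
            iterations=2000, seed=5,
        )
        np.testing.assert_allclose(res.expected_slope, SMALL_GRID * ratio)
        dev = np.abs(res.mean_slope - res.expected_slope)
        assert np.all(dev <= 5 * res.mc_se_slope)

    def test_compressed_slope_at_small_ratio(self):
        spec = CovarianceSpec(0.0, 0.0, 2.5, 2.5, 0.0)
        res = run_independent_sweep(
            spec, rho_grid=np.array([-0.6]), variance_ratio=0.5,
            iterations=4000, seed=6,
        )
        assert res.mean_slope[0] == pytest.approx(-0.3, abs=5 * res.mc_se_slope[0])

    def test_requires_positive_ratio(self):
        spec = CovarianceSpec(0.0, 0.0, 2.5, 2.5, 0.0)
        with pytest.raises(ValueError):
            run_independent_sweep(spec, variance_ratio=0.0)


class TestSharedErrorStudy:
    def test_population_slopes_near_analytic(self, shared_params):
        res = run_shared_error_study(shared_params, seed=2, iterations=2000)
        exp = shared_error_expected_slopes(shared_params)
        # population of 1000: slope SEs are ~0.015-0.022
        assert res.population_slopes.i_on_e == pytest.approx(exp.i_on_e, abs=0.08)
        assert res.population_slopes.e_on_a == pytest.approx(exp.e_on_a, abs=0.10)
        assert res.population_slopes.i_on_a == pytest.approx(exp.i_on_a, abs=0.10)

    def test_bootstrap_distributions_center_on_population_slopes(self, shared_params):
        res = run_shared_error_study(shared_params, seed=2, iterations=4000)
        for which in ("i_on_e", "e_on_a", "i_on_a"):
            lo, hi = res.iqr(which)
            assert lo <= getattr(res.population_slopes, which) <= hi

    def test_noiseless_population_slope_is_minus_capacity(self):
        params = SharedErrorParams(r=30, p_i=0.65, mu_E=12, sigma_E=4,
                                   tau_I=0, tau_E=0)
        res = run_shared_error_study(params, seed=1, iterations=100)
        assert res.population_slopes.i_on_e == pytest.approx(-0.65, abs=1e-10)

    def test_doubling_iterations_extends_bootstrap(self, shared_params):
        short = run_shared_error_study(shared_params, seed=9, iterations=300)
        long = run_shared_error_study(shared_params, seed=9, iterations=600)
        np.testing.assert_array_equal(short.slopes_i_on_e, long.slopes_i_on_e[:300])
        np.testing.assert_array_equal(short.slopes_i_on_a, long.slopes_i_on_a[:300])

    def test_subsample_larger_than_population_rejected(self, shared_params):
        with pytest.raises(ValueError):
            run_shared_error_study(shared_params, population_n=20, n_sub=25)


class TestLooseAdditivity:
    SPEC = CovarianceSpec(0.0, 0.0, 2.5, 2.5, -0.5)

    def test_zero_noise_slope_is_exactly_one(self):
        res = run_loose_additivity_study(
            self.SPEC, noise_grid=np.array([0.0]), iterations=200, seed=1
        )
        np.testing.assert_allclose(res.slopes, 1.0, atol=1e-9)

    def test_median_slope_follows_attenuation_prediction(self):
        res = run_loose_additivity_study(
            self.SPEC, noise_grid=np.array([1.0, 2.5, 4.0]),
            iterations=4000, seed=2,
        )
        med = res.median_slope()
        se_med = 1.2533 * res.slopes.std(axis=1, ddof=1) / np.sqrt(res.iterations)
        assert np.all(np.abs(med - res.predicted_slope) <= 3 * se_med)
        # attenuation is monotone in noise
        assert med[0] > med[1] > med[2]

    def test_reliability_half_construction(self):
        # total noise variance = true composite variance -> predicted 0.5
        res = run_loose_additivity_study(
            self.SPEC, noise_grid=np.array([np.sqrt(6.25 / 2)]),
            iterations=100, seed=3,
        )
        assert res.predicted_slope[0] == pytest.approx(0.5)

    def test_doubling_iterations_extends_each_condition(self):
        short = run_loose_additivity_study(
            self.SPEC, noise_grid=np.array([2.0]), iterations=250, seed=4
        )
        long = run_loose_additivity_study(
            self.SPEC, noise_grid=np.array([2.0]), iterations=500, seed=4
        )
        np.testing.assert_array_equal(short.slopes[0], long.slopes[0, :250])

    def test_summary_table_contents(self):
        res = run_loose_additivity_study(
            self.SPEC, noise_grid=np.array([0.0, 2.0]), iterations=100, seed=5
        )
        summ = res.summary()
        assert list(summ["noise_sd_deg"]) == [0.0, 2.0]
        assert np.all(summ["q25"] <= summ["median_slope"])
        assert np.all(summ["median_slope"] <= summ["q75"])


class TestResidualDiagnostics:
    def _triad(self, i, e, a):
        return TriadSample(np.asarray(i, float), np.asarray(e, float),
                           np.asarray(a, float), "independent", 0)

    def test_additive_data_gives_exact_zeros(self, spec_ae):
        from slopebench import make_subtractive_triad

        diag = residual_diagnostics(make_subtractive_triad(spec_ae, 100, seed=1))
        assert diag.mean_residual == 0.0
        assert (diag.corr_with_i, diag.corr_with_e,
                diag.corr_with_product, diag.corr_with_sum) == (0, 0, 0, 0)

    def test_multiplicative_gating_leaves_product_fingerprint(self, rng):
        i = rng.normal(10, 2, 500)
        e = rng.normal(8, 3, 500)
        diag = residual_diagnostics(self._triad(i, e, i + e - 0.02 * i * e))
        assert diag.corr_with_product < 0

    def test_pure_noise_residual_is_centered(self, rng):
        i = rng.normal(10, 2, 2000)
        e = rng.normal(8, 3, 2000)
        eps = rng.normal(0, 1, 2000)
        diag = residual_diagnostics(self._triad(i, e, i + e + eps))
        assert abs(diag.mean_residual) <= 3 / np.sqrt(2000)
        for c in (diag.corr_with_i, diag.corr_with_e,
                  diag.corr_with_product, diag.corr_with_sum):
            assert -1.0 <= c <= 1.0

    def test_needs_three_individuals(self):
        with pytest.raises(ValueError):
            residual_diagnostics(self._triad([1, 2], [3, 4], [4, 6]))
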