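"""Age-regression families, model selection, percentile bands."""

import numpy as np
import pytest

from t1norm import (
    CohortConfig,
    default_region_table,
    design_covariate,
    fit_family,
    parameter_recovery_report,
    percentile_bands,
    sample_subject,
    select_model,
    true_t1,
)


def brute_force_power_fit(ages, y):
    """Independent oracle: plain numpy least squares for every n = 1..30."""
    best = None
    m = len(ages)
    for n in range(1, 31):
        x = ages ** (-n / 10.0)
        X = np.column_stack([np.ones(m), x])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_res = resid @ resid
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot
        adj = 1 - (1 - r2) * (m - 1) / (m - 2)
        if best is None or adj > best[0] + 1e-15:
            best = (adj, n, beta[1], beta[0])
    return best  # (adj_r2, n, slope, intercept)


class TestDesignCovariate:
    @pytest.mark.parametrize(
        "family,kw,age,expected",
        [
            ("power_n10", {"n": 10}, 2.0, 0.5),
            ("logarithmic", {}, 1.0, 0.0),
            ("square_root", {}, 9.0, 3.0),
            ("linear", {}, 7.5, 7.5),
            ("exponential", {"tau": 2.0}, 2.0, np.exp(-1.0)),
        ],
    )
    def test_transforms(self, family, kw, age, expected):
        assert design_covariate(age, family, **kw) == pytest.approx(expected)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            design_covariate(0.0, "linear")


class TestFitFamily:
    def test_noise_free_power_data_identified_exactly(self):
        ages = np.linspace(0.2, 18, 60)
        y = 800.0 * ages**-0.8 + 700.0
        fit = fit_family(ages, y, "power_n10")
        assert fit.n_tenths == 8
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.residual_sd_ms == pytest.approx(0.0, abs=1e-6)
        assert fit.a == pytest.approx(800.0)
        assert fit.b == pytest.approx(700.0)

    def test_adjusted_r2_formula(self):
        # hand value: R2=0.9, n_obs=10, 1 predictor -> 1 - 0.1*9/8 = 0.8875
        rng = np.random.default_rng(0)
        # construct data with known raw R2 via projection is fiddly; instead
        # verify against the brute-force oracle on random data
        ages = rng.uniform(0.3, 18, 10)
        y = 500 * ages**-0.6 + 900 + rng.normal(0, 40, 10)
        fit = fit_family(ages, y, "power_n10")
        oracle = brute_force_power_fit(ages, y)
        assert fit.adj_r2 == pytest.approx(oracle[0], abs=1e-10)
        assert fit.n_tenths == oracle[1]
        assert 1 - (1 - 0.9) * 9 / 8 == pytest.approx(0.8875)

    def test_grid_search_matches_brute_force_on_random_datasets(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            ages = rng.uniform(0.2, 18, 40)
            y = (
                rng.uniform(100, 900) * ages ** (-rng.integers(1, 25) / 10)
                + rng.uniform(500, 1500)
                + rng.normal(0, rng.uniform(5, 80), 40)
            )
            fit = fit_family(ages, y, "power_n10")
            adj, n, slope, intercept = brute_force_power_fit(ages, y)
            assert fit.n_tenths == n
            assert fit.adj_r2 == pytest.approx(adj, abs=1e-10)
            assert fit.a == pytest.approx(slope, rel=1e-8)
            assert fit.b == pytest.approx(intercept, rel=1e-8)

    def test_constant_values_still_fit_with_nonpositive_adj_r2(self):
        ages = np.linspace(1, 18, 20)
        fit = fit_family(ages, np.full(20, 1000.0), "linear")
        assert np.isfinite(fit.adj_r2) and fit.adj_r2 <= 0

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError):
            fit_family(np.full(10, 5.0), np.arange(10.0), "linear")

    def test_residual_sd_definition(self):
        rng = np.random.default_rng(4)
        ages = np.linspace(0.5, 18, 50)
        y = 3 * ages + 5 + rng.normal(0, 2, 50)
        fit = fit_family(ages, y, "linear")
        resid = y - (fit.a * ages + fit.b)
        assert fit.residual_sd_ms == pytest.approx(
            np.sqrt(np.sum(resid**2) / 48), rel=1e-9
        )


class TestSelectModel:
    def test_linear_data_selects_linear(self):
        ages = np.linspace(0.5, 18, 50)
        fit = select_model(ages, 3 * ages + 5)
        # exact linear data may tie with a family reproducing a line; the
        # documented priority then applies, but adj R2 must be ~1 either way
        assert fit.adj_r2 == pytest.approx(1.0)
        if fit.family != "linear":
            lin = fit_family(ages, 3 * ages + 5, "linear")
            assert fit.adj_r2 >= lin.adj_r2

    def test_selected_model_dominates_all_families(self):
        rng = np.random.default_rng(23)
        ages = rng.uniform(0.2, 18, 80)
        y = 400 * ages**-0.4 + 1000 + rng.normal(0, 30, 80)
        best = select_model(ages, y)
        for family in ("linear", "logarithmic", "square_root", "exponential",
                       "power_n10"):
            assert best.adj_r2 >= fit_family(ages, y, family).adj_r2 - 1e-12

    def test_power_family_selected_on_default_cohort(self):
        cfg = CohortConfig(master_seed=19)
        subs = [sample_subject(cfg, i) for i in range(cfg.n_subjects)]
        ages = np.array([s.age_years for s in subs])
        for reg in cfg.regions:
            if reg.age_independent:
                continue
            y = np.array([s.true_t1_by_region[reg.name] for s in subs])
            assert select_model(ages, y).family == "power_n10", reg.name

    def test_age_independent_region_flagged_under_the_null(self):
        cfg = CohortConfig(master_seed=19)
        subs = [sample_subject(cfg, i) for i in range(cfg.n_subjects)]
        ages = np.array([s.age_years for s in subs])
        y = np.array([s.true_t1_by_region["bulbus_oculi"] for s in subs])
        fit = select_model(ages, y)
        assert fit.adj_r2 < 0.2
        assert fit.age_independent


class TestPercentileBands:
    def test_zero_residual_sd_bands_collapse_to_mean(self):
        ages = np.linspace(0.2, 18, 60)
        fit = fit_family(ages, 800 * ages**-0.8 + 700, "power_n10")
        bands = percentile_bands(fit, np.linspace(1, 18, 10))
        np.testing.assert_allclose(bands.p2_5_ms, bands.mean_t1_ms, atol=1e-4)
        np.testing.assert_allclose(bands.p97_5_ms, bands.mean_t1_ms, atol=1e-4)

    def test_band_width_is_2z_times_residual_sd(self):
        rng = np.random.default_rng(2)
        ages = np.linspace(0.3, 18, 100)
        y = 400 * ages**-0.4 + 1000 + rng.normal(0, 25, 100)
        fit = fit_family(ages, y, "power_n10")
        bands = percentile_bands(fit, np.array([1.0, 9.0]))
        width = bands.p97_5_ms - bands.p2_5_ms
        assert np.allclose(width, 2 * 1.959964 * fit.residual_sd_ms)

    def test_coverage_converges_to_95_percent_with_normal_residuals(self):
        # homoscedastic synthetic data: empirical coverage -> 0.95
        rng = np.random.default_rng(31)
        ages = rng.uniform(0.3, 18, 5000)
        y = 400 * ages**-0.4 + 1000 + rng.normal(0, 30, 5000)
        fit = fit_family(ages, y, "power_n10")
        pred = fit.predict(ages)
        half = 1.959964 * fit.residual_sd_ms
        coverage = np.mean(np.abs(y - pred) <= half)
        assert coverage == pytest.approx(0.95, abs=0.01)


class TestParameterRecoveryReport:
    def test_noise_free_cohort_recovers_generator_exactly(self):
        regions = default_region_table()
        ages = np.linspace(0.25, 18, 80)
        fits = {}
        for reg in regions:
            if reg.age_independent:
                continue
            fits[reg.name] = fit_family(ages, true_t1(reg, ages), "power_n10",
                                        region=reg.name)
        report = parameter_recovery_report(regions, fits)
        assert len(report) == 8  # age-dependent regions only
        assert (report.fitted_n == report.true_n).all()
        assert np.allclose(report.a_error, 0, atol=1e-6)
        assert np.allclose(report.b_error, 0, atol=1e-6)
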