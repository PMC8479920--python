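"""Synthetic cohort generator: stratum moments, structure, mortality targets."""

import numpy as np
import pandas as pd
import pytest

from sodiumsim.population import (
    AGE_BAND_LABELS,
    ConfigurationError,
    ExposureDistributionParams,
    MortalityRateParams,
    age_band_index,
    draw_sbp,
    generate_population,
    make_mortality_targets,
    make_population_structure,
)

N_AGES = 60  # single ages 30..89


class TestGeneratePopulation:
    def test_deterministic_under_fixed_seed(self, exposure_params):
        a = generate_population(2_000, 2013, exposure_params, seed=99)
        b = generate_population(2_000, 2013, exposure_params, seed=99)
        assert np.array_equal(a.sodium_total, b.sodium_total)
        assert np.array_equal(a.sbp, b.sbp)
        assert np.array_equal(a.age, b.age)
        c = generate_population(2_000, 2013, exposure_params, seed=100)
        assert not np.array_equal(a.sodium_total, c.sodium_total)

    def test_population_sodium_mean_twice_who_limit(self, big_cohort):
        # national mean intake sits at about double the 2 g/day guideline
        assert big_cohort.sodium_total.mean() == pytest.approx(4.0, abs=0.1)

    def test_source_share_means(self, big_cohort):
        # ~35% of sodium from processed foods, >55% from table salt
        assert big_cohort.processed_share.mean() == pytest.approx(0.35, abs=0.01)
        assert big_cohort.discretionary_share.mean() > 0.54

    def test_source_shares_sum_to_one(self, big_cohort):
        total = big_cohort.shares.sum(axis=1)
        assert np.all(np.abs(total - 1.0) < 1e-9)

    def test_stratum_sodium_moments_converge(self, exposure_params):
        cohort = generate_population(100_000, 2013, exposure_params, seed=3)
        band = cohort.age_band
        for sex in (0, 1):
            for b in range(4):  # the well-populated bands
                sel = (cohort.sex == sex) & (band == b)
                n = sel.sum()
                sample = cohort.sodium_total[sel]
                target = exposure_params.sodium_mean[sex][b]
                se = sample.std() / np.sqrt(n)
                assert abs(sample.mean() - target) < 3 * se

    def test_invalid_stratum_parameters_name_the_stratum(self):
        params = ExposureDistributionParams()
        bad = np.asarray(params.sodium_mean).copy()
        bad[1, 2] = -1.0
        params.sodium_mean = bad
        with pytest.raises(ConfigurationError, match="female.*50-59"):
            generate_population(10, 2013, params, seed=0)

    def test_rejects_nonpositive_n(self, exposure_params):
        with pytest.raises(ValueError):
            generate_population(0, 2013, exposure_params, seed=0)


class TestDrawSbp:
    def test_median_near_published_baseline(self, big_cohort):
        assert np.median(big_cohort.sbp) == pytest.approx(127.7, abs=0.15)

    def test_zero_sd_returns_stratum_mean(self, rng):
        params = ExposureDistributionParams(sbp_sd=(0.0, 0.0))
        age = np.full(100, 50)
        sodium = np.full(100, params.sodium_mean[0][2])
        draws = draw_sbp(age, np.zeros(100, dtype=int), sodium, params, rng)
        assert np.allclose(draws, params.sbp_at_50[0])

    def test_age_slope_recovered_from_samples(self, exposure_params, rng):
        n = 10_000
        sodium = np.full(n, 4.7)
        young = draw_sbp(np.full(n, 35), np.zeros(n, int), sodium, exposure_params, rng)
        old = draw_sbp(np.full(n, 55), np.zeros(n, int), sodium, exposure_params, rng)
        diff = old.mean() - young.mean()
        expected = 2 * exposure_params.sbp_slope_per_decade
        se = np.sqrt(old.var() / n + young.var() / n)
        assert abs(diff - expected) < 3 * se

    def test_clipped_to_physiological_range(self, big_cohort):
        assert big_cohort.sbp.min() >= 70.0
        assert big_cohort.sbp.max() <= 250.0


class TestPopulationStructure:
    def test_pure_ageing_identity_with_zero_growth(self):
        base = np.full((N_AGES, 2), 100.0)
        s = make_population_structure(base, 0.0, range(2013, 2033))
        assert s.count(2032, 49, 0) == s.count(2013, 30, 0)
        assert s.count(2022, 45, 1) == s.count(2013, 36, 1)

    def test_geometric_growth_of_totals(self):
        base = np.full((N_AGES, 2), 50.0)
        s = make_population_structure(base, 0.01, range(2013, 2033))
        ratio = s.total(2032) / s.total(2013)
        assert ratio == pytest.approx(1.01**19, rel=1e-9)

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            make_population_structure(np.ones((N_AGES, 2)), 0.0, [])

    def test_negative_counts_rejected(self):
        bad = np.ones((N_AGES, 2))
        bad[5, 0] = -1
        with pytest.raises(ValueError):
            make_population_structure(bad, 0.0, [2013, 2014])


class TestMortalityTargets:
    def test_zero_trend_zero_noise_constant_forecast(self):
        params = MortalityRateParams(
            trends={"chd": 0.0, "stroke": 0.0, "other": 0.0}, noise_sd=0.0
        )
        t = make_mortality_targets(params, range(2013, 2033), seed=0)
        base = params.base_rates["chd"][0, 2]
        for year in (2013, 2020, 2032):
            assert t.rate(year, 0, 2, "chd") == pytest.approx(base, rel=1e-9)

    def test_log_linear_forecast_closed_form(self):
        params = MortalityRateParams(
            trends={"chd": -0.02, "stroke": -0.02, "other": -0.02}, noise_sd=0.0
        )
        t = make_mortality_targets(params, [2010, 2026], seed=0)
        base = params.base_rates["stroke"][1, 3]
        # ten years into the forecast window relative to the 2016 seam
        assert t.rate(2026, 1, 3, "stroke") == pytest.approx(
            base * np.exp(-0.02 * 26), rel=1e-6
        )
        assert t.rate(2026, 1, 3, "stroke") / t.rate(2010, 1, 3, "stroke") == pytest.approx(
            np.exp(-0.02 * 16), rel=1e-6
        )

    def test_reproducible_with_noise(self):
        params = MortalityRateParams(noise_sd=0.05)
        a = make_mortality_targets(params, range(2013, 2033), seed=4)
        b = make_mortality_targets(params, range(2013, 2033), seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_rates_monotone_in_age(self):
        t = make_mortality_targets(MortalityRateParams(noise_sd=0.0), [2020], seed=0)
        for cause in ("chd", "stroke", "other"):
            rates = t.rate_array(2020, cause)
            assert np.all(np.diff(rates, axis=1) > 0)

    def test_all_cause_is_sum_of_causes(self):
        t = make_mortality_targets(MortalityRateParams(), [2015, 2025], seed=1)
        total = t.all_cause_rate(2025, 0, 4)
        parts = sum(t.rate(2025, 0, 4, c) for c in ("chd", "stroke", "other"))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_explosive_trend_rejected(self):
        params = MortalityRateParams(
            trends={"chd": 0.2, "stroke": 0.0, "other": 0.0}, noise_sd=0.0
        )
        with pytest.raises(ConfigurationError):
            make_mortality_targets(params, range(2013, 2033), seed=0)


def test_age_band_index_boundaries():
    assert list(age_band_index(np.array([30, 39, 40, 79, 80, 95]))) == [0, 0, 1, 4, 5, 5]
    assert len(AGE_BAND_LABELS) == 6
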