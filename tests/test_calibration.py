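"""Statistical layer: fixed-ratio fits, standard curves, polynomial error,
published-data comparison.  Independent oracles: closed-form log identities,
a brute-force paired t-statistic, and Monte Carlo bands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcnmeter import (
    ChamberSpec,
    DryFreshConversion,
    FixedRatioCalibration,
    InsufficientDataError,
    PolynomialTrendError,
    StandardCurve,
    convert_published,
    fixed_ratio_fit,
    paired_species_comparison,
    polynomial_error,
    standard_curve_fit,
)
from hcnmeter.datasets import load_published_comparison


class TestFixedRatio:
    def test_identity_methods(self):
        x = [1.0, 2.5, 7.0, 30.0]
        fit = fixed_ratio_fit(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.ratio == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_fixed_ratio_any_spread(self):
        b = np.array([0.3, 1.0, 4.0, 9.0, 55.0])
        fit = fixed_ratio_fit(10.2 * b, b)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(math.log10(10.2), abs=1e-10)
        assert fit.ratio == pytest.approx(10.2, rel=1e-9)

    def test_printed_intercept_ratio_identity(self):
        assert 10**0.16 == pytest.approx(1.45, abs=0.005)
        assert 10**1.01 == pytest.approx(10.2, abs=0.05)
        fit = fixed_ratio_fit(1.45 * np.array([1.0, 3, 10, 40]), [1.0, 3, 10, 40])
        assert fit.intercept == pytest.approx(0.16, abs=0.002)

    def test_ratio_equals_power_of_intercept(self):
        rng = np.random.default_rng(7)
        b = rng.lognormal(0, 1, 20)
        a = 3.3 * b * rng.lognormal(0, 0.2, 20)
        fit = fixed_ratio_fit(a, b)
        assert fit.ratio == 10**fit.intercept
        assert fit.n_pairs == 20

    def test_zero_pairs_dropped_then_insufficient(self):
        fit = fixed_ratio_fit([1.0, 2.0, 4.0, 0.0], [1.0, 2.0, 4.0, 5.0])
        assert fit.n_pairs == 3
        with pytest.raises(InsufficientDataError):
            fixed_ratio_fit([0.0, 0.0, 1.0, 2.0], [1.0, 1.0, 1.0, 2.0])

    def test_symmetric_consistency_near_perfect_fit(self):
        rng = np.random.default_rng(11)
        b = rng.lognormal(0, 1, 40)
        a = 5.0 * b * rng.lognormal(0, 0.01, 40)
        ab = fixed_ratio_fit(a, b)
        ba = fixed_ratio_fit(b, a)
        assert ab.intercept == pytest.approx(-ba.intercept, abs=0.01)

    def test_slope_tests_are_distinct(self):
        rng = np.random.default_rng(3)
        b = rng.lognormal(0, 1, 30)
        a = 2.0 * b * rng.lognormal(0, 0.05, 30)
        est = FixedRatioCalibration().fit(b, a)
        # slope ≈ 1: strongly nonzero, not distinguishable from 1
        assert est.p_slope_vs_zero_ < 1e-6
        assert est.p_slope_vs_one_ > 0.05

    def test_median_ratio_recovery_monte_carlo(self):
        """Lognormal-noise paired methods recover the true ratio (median of
        200 seeded replicates within 5%) for both observed ratios."""
        for rho in (1.45, 10.2):
            ratios = []
            for seed in range(200):
                rng = np.random.default_rng(seed)
                b = rng.lognormal(0, 1, 30)
                a = rho * b * 10 ** rng.normal(0, 0.1, 30)
                ratios.append(fixed_ratio_fit(a, b).ratio)
            assert np.median(ratios) == pytest.approx(rho, rel=0.05)


class TestStandardCurve:
    def test_exact_line_recovered(self):
        ppm = np.array([8, 30, 70, 100, 140, 171], float)
        mass = 0.027 * ppm + 0.01
        fit = standard_curve_fit(mass, ppm, ChamberSpec.cup())
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope_mg_per_ppm == pytest.approx(0.027, rel=1e-9)
        assert fit.slope_ug_hcn_per_ppm == pytest.approx(0.027 * 59.0949, rel=1e-4)

    def test_noisy_curve_r2(self):
        # amygdalin 0.2-4.7 mg spanning 8-171 ppm with 2% proportional noise
        rng = np.random.default_rng(0)
        mass = np.linspace(0.2, 4.7, 6)
        ppm = mass / 4.7 * 171 * rng.normal(1, 0.02, 6)
        fit = standard_curve_fit(mass, ppm, ChamberSpec.cup())
        assert fit.r_squared >= 0.97
        assert fit.n == 6

    def test_inverse_prediction_zero(self):
        ppm = np.array([10.0, 50, 100, 150])
        est = StandardCurve().fit(ppm, 0.03 * ppm)
        assert est.predict_mass(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_ppm_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            standard_curve_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            standard_curve_fit([1.0, 2.0], [5.0, 9.0])


class TestPolynomialError:
    def test_exact_quartic_zero_error(self):
        x = np.arange(1, 12, dtype=float)
        y = 0.3 + 0.2 * x - 0.05 * x**2 + 0.004 * x**3 - 0.0001 * x**4
        res = polynomial_error(x, y, degree=4)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)
        assert res.pct_error == pytest.approx(0.0, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0)

    def test_printed_percentage_arithmetic(self):
        assert 100 * 0.137 / 5 == pytest.approx(2.74)
        assert round(100 * 0.137 / 5, 1) == 2.7

    def test_scale_invariance_of_pct_error(self):
        rng = np.random.default_rng(5)
        x = np.arange(11, dtype=float)
        y = 1 + x - 0.1 * x**2 + rng.normal(0, 0.3, 11)
        a = polynomial_error(x, y)
        b = polynomial_error(x, 1000 * y)
        assert a.pct_error == pytest.approx(b.pct_error, rel=1e-9)

    def test_rmse_tracks_noise_sigma(self):
        """Median RMSE over 200 seeded replicates of quartic + N(0, σ) noise
        lies in [0.5σ, 1.5σ] (the OLS fit absorbs ~5/11 of the variance)."""
        sigma = 0.4
        x = np.arange(11, dtype=float)
        rmses = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = 2 + 0.5 * x - 0.02 * x**3 + rng.normal(0, sigma, x.size)
            rmses.append(polynomial_error(x, y).rmse)
        assert 0.5 * sigma <= np.median(rmses) <= 1.5 * sigma

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            polynomial_error([1, 2, 3, 4, 5], [1.0, 2, 3, 4, 5], degree=4)

    def test_raw_range_option(self):
        rng = np.random.default_rng(9)
        x = np.arange(11, dtype=float)
        y = x + rng.normal(0, 0.5, 11)
        fitted = PolynomialTrendError(use_raw_range=False).fit(x, y).result_()
        raw = PolynomialTrendError(use_raw_range=True).fit(x, y).result_()
        assert raw.curve_range >= fitted.curve_range


class TestPublishedComparison:
    def test_identical_vectors(self):
        cmp = paired_species_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.mean_difference == 0.0
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_reference_table_statistics(self):
        df = load_published_comparison()
        cmp = paired_species_comparison(
            df["converted_published_umol_per_g"], df["calibrated_cup_umol_per_g"]
        )
        assert cmp.df == 7
        assert cmp.t_statistic == pytest.approx(-1.29, abs=0.01)
        assert cmp.p_value == pytest.approx(0.24, abs=0.01)
        assert cmp.r_squared == pytest.approx(0.93, abs=0.005)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_t_statistic_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        a = rng.normal(5, 2, n)
        b = a + rng.normal(0.3, 1.0, n)
        cmp = paired_species_comparison(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        assert cmp.t_statistic == pytest.approx(t_oracle, abs=1e-10)
        assert cmp.df == n - 1


class TestDryFreshConversion:
    def test_zero(self):
        assert convert_published(0.0) == 0.0

    def test_reference_species_values(self):
        conv = DryFreshConversion()
        assert convert_published(4474, conv) == pytest.approx(34.42, abs=0.01)
        assert convert_published(1542, conv) == pytest.approx(11.86, abs=0.01)

    def test_frozen_factor_is_the_zero_intercept_fit(self):
        """The default combined factor equals the zero-intercept least-squares
        map from the dry-weight column onto the converted column."""
        df = load_published_comparison()
        x = df["published_dry_ug_per_g"].to_numpy(float)
        y = df["converted_published_umol_per_g"].to_numpy(float)
        factor = float((x * y).sum() / (x * x).sum())
        assert DryFreshConversion().combined_factor == pytest.approx(factor, rel=1e-4)
        assert 0 < DryFreshConversion().dry_to_fresh_mass_ratio < 1

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            DryFreshConversion(combined_factor=0.5)  # implies dry:fresh > 1
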