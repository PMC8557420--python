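"""Closed-form densities, moments, limits, and the segment<->ALD duality."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import admixpulse as ap


class TestSegmentDensities:
    @pytest.mark.parametrize(
        "l, t_m, expected",
        [
            (0.0, 1500.0, 1500.0),
            (1.0 / 1500.0, 1500.0, 1500.0 * np.exp(-1.0)),
            (0.001, 500.0, 500.0 * np.exp(-0.5)),
        ],
    )
    def test_simple_pdf_values(self, l, t_m, expected):
        assert ap.segment_pdf_simple(l, t_m) == pytest.approx(expected, rel=1e-12)

    def test_extended_pdf_at_zero_is_lomax_intercept(self):
        # (k+1)/scale with scale k/t_m
        assert ap.segment_pdf_extended(0.0, 1500.0, 4.0) == pytest.approx(1875.0)

    def test_extended_pdf_matches_scipy_lomax(self):
        """Independent oracle: same density as scipy's Lomax(k+1, scale k/t_m)."""
        l = np.linspace(0.0, 0.02, 101)
        for t_m, k in [(1500.0, 36.0), (450.0, 5.0625), (100.0, 2.0)]:
            ours = ap.segment_pdf_extended(l, t_m, k)
            ref = stats.lomax.pdf(l, c=k + 1.0, scale=k / t_m)
            np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_large_k_limit_recovers_exponential(self):
        l = np.linspace(0.0, 0.01, 200)
        ext = ap.segment_pdf_extended(l, 1500.0, 1e8)
        simple = ap.segment_pdf_simple(l, 1500.0)
        np.testing.assert_allclose(ext, simple, rtol=1e-5)

    def test_constant_migration_is_k1_tm_inverse_m(self):
        """k = 1, t_m = 1/m gives the last-migration form 2 m^2 / (m + l)^3."""
        m = 0.002
        l = np.linspace(0.0, 2000.0, 50)
        ours = ap.segment_pdf_extended(l, 1.0 / m, 1.0)
        np.testing.assert_allclose(ours, 2.0 * m**2 / (m + l) ** 3, rtol=1e-12)

    @pytest.mark.parametrize("t_m, k", [(1500.0, 36.0), (450.0, 5.0625), (50.0, 1.0)])
    def test_pdf_normalizes(self, t_m, k):
        total, _ = integrate.quad(
            lambda x: ap.segment_pdf_extended(x, t_m, k), 0, np.inf, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [dict(l=-0.1, t_m=100.0), dict(l=0.1, t_m=0.0),
                                     dict(l=0.1, t_m=-5.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            ap.segment_pdf_simple(bad["l"], bad["t_m"])
        with pytest.raises(ValueError):
            ap.segment_pdf_extended(bad["l"], bad["t_m"], 4.0)


class TestMoments:
    def test_mean_is_inverse_tm_for_all_k(self):
        for k in [1.5, 2.0, 36.0, 1e4, 1e8]:
            mean, _ = ap.segment_moments(1500.0, k)
            assert mean == pytest.approx(1.0 / 1500.0, rel=1e-12)

    def test_variance_formula(self):
        _, var = ap.segment_moments(1500.0, 2.0)
        assert var == pytest.approx(3.0 / 1500.0**2, rel=1e-12)

    def test_variance_decreases_in_k_to_simple_limit(self):
        ks = [2.0, 5.0, 36.0, 1e3, 1e8]
        variances = [ap.segment_moments(1500.0, k)[1] for k in ks]
        assert np.all(np.diff(variances) < 0)
        assert variances[-1] == pytest.approx(1.0 / 1500.0**2, rel=1e-6)

    def test_variance_infinite_at_k1(self):
        with pytest.raises(ValueError, match="infinite"):
            ap.segment_moments(1500.0, 1.0)

    def test_monte_carlo_moments(self):
        p = ap.PulseParams.from_duration(1500.0, 1000.0)
        segs = ap.simulate_segments(10**6, p, seed=5)
        mean, var = ap.segment_moments(p.t_m, p.k)
        se_mean = np.sqrt(var / segs.n)
        assert abs(segs.lengths.mean() - mean) < 3 * se_mean
        # SE of the sample variance via the fourth moment of the sample
        m4 = np.mean((segs.lengths - segs.lengths.mean()) ** 4)
        se_var = np.sqrt((m4 - var**2) / segs.n)
        assert abs(segs.lengths.var() - var) < 3 * se_var


class TestTimeAndMigrationDensities:
    def test_time_density_mean(self):
        t_m, k = 1500.0, 36.0
        mean, _ = integrate.quad(
            lambda t: t * ap.segment_time_pdf(t, t_m, k), 0, np.inf, limit=200
        )
        assert mean == pytest.approx((k + 1) / k * t_m, rel=1e-8)

    def test_time_density_normalizes(self):
        total, _ = integrate.quad(
            lambda t: ap.segment_time_pdf(t, 1500.0, 36.0), 0, np.inf, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_constant_migration_time_density_is_gamma_2_m(self):
        m = 0.01
        t = np.linspace(0.0, 1000.0, 50)
        ours = ap.segment_time_pdf(t, 1.0 / m, 1.0)
        np.testing.assert_allclose(ours, stats.gamma.pdf(t, a=2, scale=1.0 / m), rtol=1e-12)

    def test_migration_density_integrates_to_alpha(self):
        # split at the mean so quad resolves the localized Gamma peak
        parts = [
            integrate.quad(
                lambda t: ap.migration_density(t, 1500.0, 36.0, alpha=0.03),
                a, b, limit=200,
            )[0]
            for a, b in [(0.0, 1500.0), (1500.0, np.inf)]
        ]
        assert sum(parts) == pytest.approx(0.03, abs=1e-8)

    def test_constant_migration_rate_is_exponential(self):
        m, alpha = 0.004, 0.03
        t = np.linspace(0.0, 2000.0, 40)
        ours = ap.migration_density(t, 1.0 / m, 1.0, alpha=alpha)
        np.testing.assert_allclose(ours, alpha * m * np.exp(-m * t), rtol=1e-12)

    def test_length_biased_migration_equals_time_density(self):
        """t * m(t), renormalized, is the entry-time density."""
        t = np.linspace(1.0, 4000.0, 400)
        t_m, k = 1500.0, 36.0
        biased = t * ap.migration_density(t, t_m, k)
        biased /= np.trapezoid(biased, t)
        expected = ap.segment_time_pdf(t, t_m, k)
        expected /= np.trapezoid(expected, t)
        np.testing.assert_allclose(biased, expected, rtol=1e-6)


class TestALDCurves:
    def test_intercept_and_background(self):
        assert ap.ald_simple(0.0, 1500.0, A=0.4, c=0.02) == pytest.approx(0.42)
        assert ap.ald_extended(0.0, 1500.0, 36.0, A=0.4, c=0.02) == pytest.approx(0.42)
        assert ap.ald_simple(10.0, 1500.0, A=1.0, c=0.02) == pytest.approx(0.02, abs=1e-12)

    def test_half_decay(self):
        l = np.log(2.0) / 1500.0
        assert ap.ald_simple(l, 1500.0, A=1.0, c=0.0) == pytest.approx(0.5)

    def test_large_k_limit(self):
        l = np.linspace(0.0, 0.02, 300)
        np.testing.assert_allclose(
            ap.ald_extended(l, 1500.0, 1e8), ap.ald_simple(l, 1500.0), rtol=1e-5
        )

    def test_constant_migration_hyperbolic_decay(self):
        m = 0.003
        l = np.linspace(0.0, 0.05, 60)
        ours = ap.ald_extended(l, 1.0 / m, 1.0, A=1.0, c=0.0)
        np.testing.assert_allclose(ours, m / (m + l), rtol=1e-12)

    @given(st.floats(0.0, 0.1), st.floats(0.0, 0.1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_extended_ald_non_increasing(self, l1, l2):
        lo, hi = sorted((l1, l2))
        assert ap.ald_extended(hi, 1500.0, 5.0) <= ap.ald_extended(lo, 1500.0, 5.0) + 1e-15


class TestSegmentALDDuality:
    def test_exponential_density_gives_exponential_ald(self):
        """int_l^inf t e^(-tx) (x-l) dx = e^(-tl)/t, so the curve is exponential."""
        t_m = 1500.0
        l = np.linspace(0.0, 0.005, 20)
        D = ap.ald_from_segment_density(lambda x: ap.segment_pdf_simple(x, t_m), l)
        np.testing.assert_allclose(D, np.exp(-t_m * l) / t_m, rtol=1e-8)

    def test_lomax_density_proportional_to_extended_ald(self):
        t_m, k = 1500.0, 36.0
        l = np.linspace(0.0, 5e-3, 100)
        D = ap.ald_from_segment_density(lambda x: ap.segment_pdf_extended(x, t_m, k), l)
        ratio = D / ap.ald_extended(l, t_m, k)
        assert ratio.max() / ratio.min() - 1.0 < 1e-4

    def test_at_zero_reduces_to_mean_segment_length(self):
        t_m = 1500.0
        D0 = ap.ald_from_segment_density(
            lambda x: ap.segment_pdf_simple(x, t_m), 0.0,
            expected_segments=7.0, genome_size=2.0,
        )
        assert D0 == pytest.approx(7.0 / (2.0 * t_m), rel=1e-8)

    def test_second_derivative_recovers_exponential_density(self):
        t_m = 1500.0
        grid = np.linspace(1e-4, 5e-3, 100)
        raw = ap.segment_density_from_ald(lambda x: np.exp(-t_m * x), grid, step=1e-6)
        dens = raw / np.trapezoid(raw, grid)
        expected = ap.segment_pdf_simple(grid, t_m)
        expected /= np.trapezoid(expected, grid)
        np.testing.assert_allclose(dens, expected, rtol=1e-3)

    def test_round_trip_lomax(self):
        """Quadrature forward, second difference back, recovers the Lomax shape."""
        t_m, k = 1500.0, 36.0
        grid = np.linspace(1e-4, 5e-3, 60)
        raw = ap.segment_density_from_ald(
            lambda x: ap.ald_extended(np.asarray(x), t_m, k), grid, step=1e-6
        )
        expected = ap.segment_pdf_extended(grid, t_m, k)
        np.testing.assert_allclose(raw / raw[0], expected / expected[0], rtol=1e-3)

    def test_constant_curve_gives_zero_density(self):
        grid = np.linspace(0.001, 0.01, 10)
        raw = ap.segment_density_from_ald(lambda x: np.full_like(np.asarray(x), 0.3), grid)
        np.testing.assert_allclose(raw, 0.0, atol=1e-6)


class TestEffectiveMigration:
    def test_constant_rate(self):
        m0 = 0.001
        got = ap.effective_migration(lambda t: m0, 1000.0)
        assert got == pytest.approx(m0 * np.exp(-m0 * 1000.0), rel=1e-8)

    def test_at_zero_is_raw_rate(self):
        assert ap.effective_migration(lambda t: 0.42, 0.0) == pytest.approx(0.42)

    def test_total_mass_is_one_minus_exp_neg_alpha(self):
        alpha = 0.03
        m = lambda t: ap.migration_density(t, 1500.0, 36.0, alpha=alpha)
        total, _ = integrate.quad(
            lambda t: ap.effective_migration(m, t), 0, 6000.0, limit=400
        )
        assert total == pytest.approx(1.0 - np.exp(-alpha), rel=1e-5)


class TestConversions:
    def test_duration_examples(self):
        assert ap.convert_duration(1500.0, 16.0) == pytest.approx(1500.0)
        assert ap.convert_shape(1500.0, 1000.0) == pytest.approx(36.0)

    @given(st.floats(1.0, 5000.0), st.floats(1.0, 1e8))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_round_trip_identity(self, t_m, k):
        t_d = ap.convert_duration(t_m, k)
        assert ap.convert_shape(t_m, t_d) == pytest.approx(k, rel=1e-12)

    def test_duration_above_4tm_rejected(self):
        with pytest.raises(ValueError, match="k < 1"):
            ap.convert_shape(100.0, 500.0)

    def test_params_from_duration(self):
        p = ap.PulseParams.from_duration(1500.0, 1000.0)
        assert p.k == pytest.approx(36.0)
        assert p.t_d == pytest.approx(1000.0)

    @pytest.mark.parametrize("kwargs", [dict(t_m=0.0), dict(t_m=1500.0, k=0.5),
                                        dict(t_m=1500.0, alpha=1.5)])
    def test_params_validation(self, kwargs):
        with pytest.raises(ValueError):
            ap.PulseParams(**kwargs)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "gens, years, ky",
        [(1682, 48_778, 49), (1526, 44_254, 44), (0, 0, 0)],
    )
    def test_generation_to_year_conversion(self, gens, years, ky):
        assert ap.generations_to_years(gens, 29.0) == pytest.approx(years)
        assert ap.generations_to_ky(gens, 29.0) == ky
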