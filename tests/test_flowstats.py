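import numpy as np
import pytest
import scipy.integrate
import scipy.stats

from cgflow.flowstats import (
    AD_CRITICAL_5PCT,
    MPModel,
    anderson_darling,
    marginal_density_summary,
    mp_cdf,
    mp_compare,
    mp_pdf,
    spectral_gap,
    standardized_fourth_moment,
    summarize_scale,
)
from cgflow.momentum import eigendecompose


class TestSpectralGap:
    def test_direct_maximum(self):
        assert spectral_gap([4.0, 1.0, 0.5]) == pytest.approx(3.0)
        assert spectral_gap([4.0, 1.0, 0.5], normalized=True) == pytest.approx(0.75)

    def test_flat_spectrum_zero_gap(self):
        assert spectral_gap([1.0, 1.0, 1.0]) == 0.0

    def test_skip_first_ignores_dominant_mode(self):
        lam = [10.0, 2.0, 1.9, 0.5]
        assert spectral_gap(lam) == pytest.approx(8.0)
        assert spectral_gap(lam, skip_first=True) == pytest.approx(1.4)

    def test_two_block_closed_form(self):
        c = np.array(
            [
                [1.0, 0.8, 0.0, 0.0],
                [0.8, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.8],
                [0.0, 0.0, 0.8, 1.0],
            ]
        )
        lam = eigendecompose(c).eigenvalues
        np.testing.assert_allclose(lam, [1.8, 1.8, 0.2, 0.2], atol=1e-12)
        assert spectral_gap(lam) == pytest.approx(1.6)
        assert spectral_gap(lam, normalized=True) == pytest.approx(8 / 9)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            spectral_gap([1.0, 2.0])

    def test_appending_smaller_tail_cannot_shrink_gap(self, rng):
        lam = np.sort(rng.uniform(0.5, 3.0, 8))[::-1]
        base = spectral_gap(lam)
        extended = np.concatenate([lam, [lam[-1] - 0.01, lam[-1] - 0.02]])
        assert spectral_gap(extended) >= base

    def test_block_spectrum_family_closed_form(self):
        """B equal blocks of size s: spectrum {1+(s-1)rho, 1-rho}, gap = s*rho."""
        for b, s, rho in [(2, 3, 0.5), (3, 4, 0.7), (4, 2, 0.3)]:
            n = b * s
            c = np.zeros((n, n))
            for k in range(b):
                c[k * s : (k + 1) * s, k * s : (k + 1) * s] = rho
            np.fill_diagonal(c, 1.0)
            lam = eigendecompose(c).eigenvalues
            expected = np.r_[np.full(b, 1 + (s - 1) * rho), np.full(n - b, 1 - rho)]
            np.testing.assert_allclose(lam, expected, atol=1e-8)
            assert spectral_gap(lam) == pytest.approx(s * rho, abs=1e-8)


class TestFourthMoment:
    def test_gaussian_reference(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert standardized_fourth_moment(x) == pytest.approx(3.0, abs=0.1)

    def test_symmetric_two_point_value_one(self):
        x = np.array([-1.0, 1.0] * 50)
        assert standardized_fourth_moment(x) == pytest.approx(1.0)

    def test_laplace_analytic_kurtosis(self):
        x = np.random.default_rng(1).laplace(size=100_000)
        assert standardized_fourth_moment(x) == pytest.approx(6.0, abs=0.3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardized_fourth_moment(np.ones(10))


class TestAndersonDarling:
    def test_matches_scipy_statistic_unadjusted(self, rng):
        import warnings

        x = rng.standard_normal(200)
        ours = anderson_darling(x, adjust=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            ref = scipy.stats.anderson(x, "norm").statistic
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_adjustment_is_exact_factor(self, rng):
        x = rng.standard_normal(64)
        n = x.size
        ratio = anderson_darling(x, adjust=True) / anderson_darling(x, adjust=False)
        assert ratio == pytest.approx(1 + 0.75 / n + 2.25 / n**2, abs=1e-12)

    def test_gaussian_quantile_sequence_small_statistic(self):
        n = 100
        x = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert anderson_darling(x) < 0.3

    def test_cauchy_sample_strongly_rejected(self):
        x = np.random.default_rng(2).standard_cauchy(500)
        assert anderson_darling(x) > 10

    def test_short_or_tied_input_rejected(self):
        with pytest.raises(ValueError):
            anderson_darling(np.arange(5.0))
        with pytest.raises(ValueError):
            anderson_darling(np.ones(20))

    def test_nominal_false_positive_rate(self, rng):
        hits = sum(
            anderson_darling(rng.standard_normal(500)) > AD_CRITICAL_5PCT for _ in range(300)
        )
        assert 0.01 < hits / 300 < 0.10


class TestMarchenkoPastur:
    def test_support_edges(self):
        m = MPModel(gamma=0.25, sigma2=1.0)
        assert m.lam_minus == pytest.approx(0.25)
        assert m.lam_plus == pytest.approx(2.25)
        assert mp_pdf(0.1, m) == 0.0
        assert mp_pdf(3.0, m) == 0.0
        assert mp_pdf(1.0, m) > 0

    def test_density_integrates_to_one(self):
        m = MPModel(gamma=0.5, sigma2=1.0)
        total, _ = scipy.integrate.quad(lambda x: mp_pdf(x, m), m.lam_minus, m.lam_plus)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_cdf_consistent_with_quadrature(self):
        m = MPModel(gamma=0.3, sigma2=2.0)
        for q in (0.25, 0.5, 0.9):
            x = m.lam_minus + q * (m.lam_plus - m.lam_minus)
            ref, _ = scipy.integrate.quad(lambda t: mp_pdf(t, m), m.lam_minus, x)
            assert mp_cdf(x, m) == pytest.approx(ref, abs=1e-4)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            MPModel(gamma=1.5)

    def test_iid_gaussian_eigenvalues_fit(self, rng):
        x = rng.standard_normal((300, 1500))
        lam = eigendecompose(np.corrcoef(x)).eigenvalues
        model, ks = mp_compare(lam, n_obs=1500)
        assert model.gamma == pytest.approx(0.2)
        assert ks < 0.05

    def test_excluding_planted_factor_improves_fit(self, rng):
        f = rng.standard_normal(1500)
        x = rng.standard_normal((200, 1500)) + 0.8 * f
        lam = eigendecompose(np.corrcoef(x)).eigenvalues
        _, ks_all = mp_compare(lam, n_obs=1500, exclude_top_frac=0.0)
        _, ks_excl = mp_compare(lam, n_obs=1500, exclude_top_frac=0.01)
        assert ks_excl < ks_all

    def test_too_few_remaining_eigenvalues(self):
        with pytest.raises(ValueError, match="10"):
            mp_compare(np.linspace(2, 1, 8), n_obs=100)


class TestDensitySummary:
    def test_identical_variables_median_is_common_density(self, rng):
        row = rng.standard_normal(2000)
        x = np.tile(row, (5, 1))
        d = marginal_density_summary(x)
        single = np.histogram(row, bins=d.bin_edges, density=True)[0]
        np.testing.assert_allclose(d.median, single)
        np.testing.assert_allclose(d.q25, d.q75)

    def test_gaussian_ensemble_matches_reference(self, rng):
        x = rng.standard_normal((50, 5000))
        d = marginal_density_summary(x)
        mask = np.abs(d.centers) < 2.5
        assert np.max(np.abs(d.median[mask] - d.gaussian[mask])) < 0.03

    def test_densities_integrate_to_one(self, rng):
        x = rng.standard_normal((10, 1000))
        d = marginal_density_summary(x)
        widths = np.diff(d.bin_edges)
        assert (d.median * widths).sum() == pytest.approx(1.0, abs=0.02)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            marginal_density_summary(rng.standard_normal((3, 50)), grid=np.array([0.0]))


def test_summarize_scale_bundles_everything(gaussian_expression):
    s = summarize_scale(gaussian_expression, scale_label=0)
    assert s.n_variables == 30
    assert s.eigenvalues is not None and s.spectral_gap is not None
    assert 0 <= s.spectral_gap_normalized <= 1
    assert s.kurtosis_per_variable.shape == (30,)
    assert s.ad_stat_per_variable.shape == (30,)
    d = s.to_dict()
    assert {"spectral_gap", "median_kurtosis", "ad_rejection_rate_5pct"} <= set(d)
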