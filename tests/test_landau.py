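"""Unit and property tests for the Landau density, fits, and BIC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from bistab import (
    delta_bic_landau,
    delta_bic_mixture,
    fit_gaussian_1d,
    fit_landau,
    fit_mixture_1d,
    ks_gof,
    landau_cdf_1d,
    landau_log_density_1d,
    landau_log_normalization_1d,
    landau_normalization_1d,
    sample_landau,
)
from bistab.landau import D_MIN, LandauFit

from helpers import quad_log_normalization


class TestNormalization:
    def test_gaussian_limit(self):
        assert landau_normalization_1d(1.0, 1e-9, 1.0) == pytest.approx(
            math.sqrt(2 * math.pi), abs=1e-4
        )
        # d = 0 exactly is the pure Gaussian
        assert landau_normalization_1d(1.0, 0.0, 1.0) == pytest.approx(
            math.sqrt(2 * math.pi), rel=1e-12
        )

    @pytest.mark.parametrize(
        "c,d,j_nu,expected",
        [
            (-4.0, 3.0, 1.0, 7.605703786318606),  # quadrature oracle
            (2.0, 1.0, 2.0, 1.1195578897284462),  # quadrature oracle
        ],
    )
    def test_frozen_quadrature_values(self, c, d, j_nu, expected):
        assert landau_normalization_1d(c, d, j_nu) == pytest.approx(
            expected, rel=1e-8
        )

    @pytest.mark.parametrize(
        "c,d,j_nu",
        [(-10.0, 1e-3, 0.1), (0.1, 0.1, 10.0), (4.0, 10.0, 1.0), (-1.0, 1.0, 1.0)],
    )
    def test_matches_adaptive_quadrature(self, c, d, j_nu):
        got = landau_log_normalization_1d(c, d, j_nu)
        assert got == pytest.approx(quad_log_normalization(c, d, j_nu), abs=1e-8)

    def test_continuity_across_c_zero(self):
        lo = landau_normalization_1d(-1e-7, 1.0, 1.0)
        hi = landau_normalization_1d(1e-7, 1.0, 1.0)
        mid = landau_normalization_1d(0.0, 1.0, 1.0)
        assert lo == pytest.approx(mid, rel=1e-6)
        assert hi == pytest.approx(mid, rel=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            landau_normalization_1d(-1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            landau_normalization_1d(1.0, 1.0, -2.0)


class TestDensity:
    def test_gaussian_limit_pointwise(self):
        ys = np.linspace(-4, 4, 41)
        got = landau_log_density_1d(ys, 1.0, 1e-9, 1.0, 0.0)
        want = stats.norm.logpdf(ys)
        assert np.max(np.abs(got - want)) < 1e-6

    @pytest.mark.parametrize("t", [0.5, 1.0, 2.0])
    def test_symmetry_about_center(self, t):
        mu = 0.7
        a = landau_log_density_1d(mu + t, -4.0, 3.0, 1.0, mu)
        b = landau_log_density_1d(mu - t, -4.0, 3.0, 1.0, mu)
        assert a == pytest.approx(b, rel=1e-12)

    def test_bistable_maxima_positions(self):
        # maxima of exp[-(c/2)Jy^2-(d/4)J^2y^4] at y = +-sqrt(-c/(dJ))
        c, d = -4.0, 3.0
        m = math.sqrt(4.0 / 3.0)
        neg = lambda y: -landau_log_density_1d(y, c, d, 1.0, 0.0)
        found = optimize.minimize_scalar(neg, bracket=(0.5, m, 2.0)).x
        assert found == pytest.approx(m, abs=1e-8)

    def test_integrates_to_one(self):
        from scipy import integrate

        for c, d in [(-4.0, 3.0), (1.0, 0.5), (0.0, 2.0)]:
            val, _ = integrate.quad(
                lambda y: np.exp(landau_log_density_1d(y, c, d, 1.3, 0.2)),
                -np.inf,
                np.inf,
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_non_normalizable_rejected(self):
        with pytest.raises(ValueError):
            landau_log_density_1d(0.0, -1.0, 0.0, 1.0, 0.0)


class TestCDF:
    def _fit(self, c, d, j_nu=1.0, mu=0.0):
        return LandauFit(c=c, d=d, mu_nu=mu, j_nu=j_nu, log_likelihood=0.0, n_samples=0)

    def test_half_mass_at_center(self):
        for c, d in [(-4.0, 3.0), (1.0, 1e-3), (2.0, 0.5)]:
            fit = self._fit(c, d, mu=0.3)
            assert landau_cdf_1d(0.3, fit) == pytest.approx(0.5, abs=1e-9)

    def test_limits(self):
        fit = self._fit(-4.0, 3.0)
        assert landau_cdf_1d(-1e6, fit) == 0.0
        assert landau_cdf_1d(1e6, fit) == 1.0

    def test_gaussian_limit_matches_normal_cdf(self):
        fit = self._fit(1.0, 1e-9)
        for y in (-2.0, 0.0, 1.0):
            assert landau_cdf_1d(y, fit) == pytest.approx(
                stats.norm.cdf(y), abs=1e-5
            )

    def test_mass_between_modes_vs_quadrature(self):
        # oracle: quad of the normalized density between the two maxima
        fit = self._fit(-4.0, 3.0)
        m = math.sqrt(4.0 / 3.0)
        got = landau_cdf_1d(m, fit) - landau_cdf_1d(-m, fit)
        assert got == pytest.approx(0.6300619114251026, abs=1e-7)

    def test_monotone(self):
        fit = self._fit(-6.0, 5.0)
        ys = np.linspace(-4, 4, 1001)
        assert np.all(np.diff(landau_cdf_1d(ys, fit)) >= 0)


class TestGaussianFit:
    def test_closed_form_three_points(self):
        fit = fit_gaussian_1d(np.array([-1.0, 0.0, 1.0]))
        assert fit.mean == pytest.approx(0.0)
        assert fit.variance == pytest.approx(2.0 / 3.0)

    def test_large_sample_recovery(self, rng):
        y = rng.normal(size=100_000)
        fit = fit_gaussian_1d(y)
        assert fit.mean == pytest.approx(0.0, abs=0.02)
        assert fit.variance == pytest.approx(1.0, abs=0.02)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_1d(np.full(10, 3.0))


class TestLandauFit:
    def test_gaussian_data_gives_near_gaussian_shape(self, rng):
        y = rng.normal(size=10_000)
        fit = fit_landau(y, j_nu=1.0 / y.var(ddof=1))
        assert fit.c == pytest.approx(1.0, abs=0.1)
        assert fit.d < 0.05  # at or near the floor
        assert not fit.is_bistable

    def test_parameter_recovery_bistable(self, rng):
        c, d = -4.0, 3.0
        y = sample_landau(10_000, c, d, 1.0, rng=rng)
        fit = fit_landau(y, j_nu=1.0)
        assert fit.c == pytest.approx(c, rel=0.15)
        assert fit.d == pytest.approx(d, rel=0.15)
        assert fit.is_bistable
        lo, hi = fit.modes()
        assert hi - fit.mu_nu == pytest.approx(math.sqrt(-fit.c / fit.d), abs=1e-10)

    def test_likelihood_dominates_gaussian_slice(self, rng):
        # the family nests the Gaussian (c=1 slice, d at floor)
        for _ in range(5):
            y = rng.normal(size=50)
            j_nu = 1.0 / y.var(ddof=1)
            fit = fit_landau(y, j_nu)
            slice_ll = float(
                np.sum(landau_log_density_1d(y, 1.0, D_MIN, j_nu, y.mean()))
            )
            assert fit.log_likelihood >= slice_ll - 1e-9

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_landau(np.full(10, 2.0), 1.0)


class TestMixtureFit:
    def test_recovery_well_separated(self, rng):
        y = np.concatenate([rng.normal(-3, 1, 5000), rng.normal(3, 1, 5000)])
        fit = fit_mixture_1d(y, seed=0)
        assert fit.loc1 == pytest.approx(-3.0, rel=0.05)
        assert fit.loc2 == pytest.approx(3.0, rel=0.05)
        assert fit.width == pytest.approx(1.0, rel=0.05)
        assert fit.weight == pytest.approx(0.5, abs=0.025)
        assert fit.loc1 <= fit.loc2

    def test_two_point_data(self):
        y = np.array([-1.0, 1.0] * 8)
        fit = fit_mixture_1d(y, seed=0)
        assert fit.loc1 == pytest.approx(-1.0, abs=1e-2)
        assert fit.loc2 == pytest.approx(1.0, abs=1e-2)
        assert fit.weight == pytest.approx(0.5, abs=1e-6)

    def test_unimodal_data_not_selected(self, rng):
        y = rng.normal(size=200)
        gauss = fit_gaussian_1d(y)
        mix = fit_mixture_1d(y, seed=0)
        dbic = delta_bic_mixture(gauss.log_likelihood, mix.log_likelihood, y.size)
        assert dbic < 6.0

    def test_cdf_is_proper(self, rng):
        fit = fit_mixture_1d(rng.normal(size=100), seed=1)
        assert fit.cdf(-1e9) == pytest.approx(0.0)
        assert fit.cdf(1e9) == pytest.approx(1.0)


class TestDeltaBIC:
    def test_worked_arithmetic(self):
        assert delta_bic_landau(0.0, 0.0, 16) == pytest.approx(-math.log(16))
        assert delta_bic_landau(0.0, 10.0, 16) == pytest.approx(20 - math.log(16))
        assert delta_bic_mixture(0.0, 0.0, 16) == pytest.approx(-2 * math.log(16))
        assert delta_bic_mixture(0.0, 10.0, 16) == pytest.approx(
            20 - 2 * math.log(16)
        )

    @given(st.integers(min_value=1, max_value=10**6), st.floats(-1e3, 1e3))
    @settings(derandomize=True, max_examples=50)
    def test_penalty_identity(self, n, ll):
        assert delta_bic_landau(ll, ll, n) == pytest.approx(-math.log(n))
        assert delta_bic_mixture(ll, ll, n) == pytest.approx(-2 * math.log(n))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            delta_bic_landau(0.0, 0.0, 0)

    def test_well_separated_detected_in_majority_of_seeds(self):
        # 16 samples from a strongly bistable density: dBIC > 6 mostly
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = sample_landau(16, -8.0, 2.0, 1.0, rng=rng)
            gauss = fit_gaussian_1d(y)
            landau = fit_landau(y, j_nu=1.0 / y.var(ddof=1))
            if delta_bic_landau(gauss.log_likelihood, landau.log_likelihood, 16) > 6:
                hits += 1
        assert hits > 50

    def test_landau_beats_mixture_near_transition(self):
        # weakly bistable data: the Landau model needs fewer parameters
        gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = sample_landau(100, -2.0, 1.0, 1.0, rng=rng)
            gauss = fit_gaussian_1d(y)
            landau = fit_landau(y, j_nu=1.0 / y.var(ddof=1))
            mix = fit_mixture_1d(y, seed=seed)
            dl = delta_bic_landau(gauss.log_likelihood, landau.log_likelihood, 100)
            dm = delta_bic_mixture(gauss.log_likelihood, mix.log_likelihood, 100)
            gaps.append(dl - dm)
        assert np.mean(gaps) > 0


class TestKS:
    def test_self_comparison_bound(self, rng):
        y = np.sort(rng.normal(size=50))
        ecdf = lambda q: np.searchsorted(y, q, side="right") / y.size
        d, _ = ks_gof(y, ecdf)
        assert d <= 1.0 / y.size + 1e-12

    def test_uniform_calibration(self, rng):
        y = rng.uniform(size=10_000)
        d, p = ks_gof(y, lambda q: np.clip(q, 0, 1))
        assert p > 0.01

    def test_non_monotone_cdf_rejected(self, rng):
        y = rng.normal(size=100)
        with pytest.raises(ValueError):
            ks_gof(y, lambda q: -np.asarray(q))

    def test_landau_sampler_matches_cdf(self, rng):
        fit = LandauFit(
            c=-4.0, d=3.0, mu_nu=0.0, j_nu=1.0, log_likelihood=0.0, n_samples=0
        )
        y = sample_landau(20_000, -4.0, 3.0, 1.0, rng=rng)
        _, p = ks_gof(y, fit.cdf)
        assert p > 0.01
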