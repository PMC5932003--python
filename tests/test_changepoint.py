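import math

import numpy as np
import pytest
from scipy.integrate import quad

from peatflux.changepoint import (
    ChangepointPriors,
    McmcSettings,
    SeriesData,
    enumerate_oracle,
    posterior_mean_curve,
    run_changepoint,
    segment_marginal_loglik,
    total_variation,
)

FAST = McmcSettings(n_iter=30_000, burn_in=6_000, thin=5)


def _step_series(n=100, switch=50, jump=1.0, sigma=0.05, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(float(n))
    y = np.where(t < switch, 0.0, jump) + rng.normal(0, sigma, n)
    return SeriesData(t, y)


class TestMarginalLoglik:
    def test_single_point_closed_form(self):
        # y = m0, sigma = v0 = 1: log N(m0 | m0, 2)
        v = segment_marginal_loglik(np.array([0.0]), 1.0, 0.0, 1.0)
        assert v == pytest.approx(-0.5 * math.log(4 * math.pi), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadrature_oracle(self, seed):
        """Closed form equals the numerically integrated Normal mixture."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0.3, 0.5, size=rng.integers(1, 6))
        sigma, m0, v0 = 0.7, 0.2, 1.3

        def integrand(mu):
            ll = -0.5 * np.sum((y - mu) ** 2) / sigma**2 - y.size * 0.5 * math.log(
                2 * math.pi * sigma**2
            )
            prior = math.exp(-0.5 * (mu - m0) ** 2 / v0) / math.sqrt(2 * math.pi * v0)
            return math.exp(ll) * prior

        numeric, _ = quad(integrand, m0 - 30, m0 + 30, limit=200)
        assert segment_marginal_loglik(y, sigma, m0, v0) == pytest.approx(
            math.log(numeric), abs=1e-6
        )

    def test_vanishing_prior_variance_recovers_fixed_mean(self):
        y = np.array([0.1, -0.2, 0.3])
        sigma, m0 = 0.5, 0.05
        fixed = -0.5 * np.sum((y - m0) ** 2) / sigma**2 - y.size * 0.5 * math.log(
            2 * math.pi * sigma**2
        )
        v = segment_marginal_loglik(y, sigma, m0, 1e-14)
        assert v == pytest.approx(fixed, abs=1e-6)

    def test_rejects_empty_segment_and_bad_scales(self):
        with pytest.raises(ValueError):
            segment_marginal_loglik(np.array([]), 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            segment_marginal_loglik(np.array([1.0]), 0.0, 0.0, 1.0)


class TestOracle:
    def test_flat_data_prefers_no_changepoint(self):
        rng = np.random.default_rng(1)
        d = SeriesData(np.arange(12.0), rng.normal(0.0, 0.2, 12))
        orc = enumerate_oracle(
            d, ChangepointPriors(k_max=2), k_max=2,
            sigma_grid=np.array([0.1, 0.2, 0.4]),
        )
        assert orc.k_posterior[0] > orc.k_posterior[1]

    def test_position_grid_label_permutation_is_irrelevant(self):
        d = _step_series(n=10, switch=5, sigma=0.1, seed=2)
        grid = d.t[:-1] + 0.5
        rng = np.random.default_rng(0)
        orc1 = enumerate_oracle(d, k_max=2, position_grid=grid)
        orc2 = enumerate_oracle(d, k_max=2, position_grid=rng.permutation(grid))
        assert np.allclose(orc1.k_posterior, orc2.k_posterior)
        assert np.allclose(orc1.gap_marginal, orc2.gap_marginal)

    def test_oracle_rejects_large_series(self):
        d = SeriesData(np.arange(40.0), np.zeros(40) + np.arange(40) * 0.01)
        with pytest.raises(ValueError):
            enumerate_oracle(d)


class TestSampler:
    def test_mcmc_matches_oracle_on_step_data(self):
        d = _step_series(n=12, switch=6, sigma=0.15, seed=3)
        sd = float(d.y.std())
        bounds = (0.05 * sd, 3.0 * sd)
        priors = ChangepointPriors(k_max=2, sigma_bounds=bounds)
        orc = enumerate_oracle(
            d, priors, k_max=2,
            sigma_grid=np.exp(np.linspace(np.log(bounds[0]), np.log(bounds[1]), 20)),
        )
        post = run_changepoint(
            d, priors, McmcSettings(n_iter=150_000, burn_in=30_000, thin=5), seed=4
        )
        assert total_variation(orc.k_posterior, post.k_posterior) < 0.05

    def test_prior_recovery_with_constant_likelihood(self):
        d = SeriesData(np.arange(300.0), np.zeros(300))
        priors = ChangepointPriors(k_max=5, sigma_bounds=(0.1, 1.0))
        post = run_changepoint(
            d, priors, McmcSettings(n_iter=200_000, burn_in=20_000, thin=5),
            seed=5, likelihood_off=True,
        )
        # positions uniform, k prior uniform -> sampled p(k) uniform on 0..5
        assert total_variation(post.k_posterior, np.full(6, 1 / 6)) < 0.02

    def test_step_data_modal_k_and_location(self):
        post = run_changepoint(_step_series(seed=6), mcmc=FAST, seed=7)
        assert int(np.argmax(post.k_posterior)) == 1
        assert 48.0 <= post.location_mode() <= 52.0
        assert post.location_mass(48.0, 52.0) > 0.6

    def test_white_noise_prefers_no_changepoint(self):
        rng = np.random.default_rng(8)
        d = SeriesData(np.arange(100.0), rng.normal(0, 1, 100))
        post = run_changepoint(d, mcmc=FAST, seed=9)
        assert int(np.argmax(post.k_posterior)) == 0

    def test_seeded_runs_are_bit_reproducible(self):
        d = _step_series(seed=10)
        p1 = run_changepoint(d, mcmc=FAST, seed=11)
        p2 = run_changepoint(d, mcmc=FAST, seed=11)
        assert np.array_equal(p1.k_posterior, p2.k_posterior)
        assert np.array_equal(p1.samples_sigma, p2.samples_sigma)
        assert np.array_equal(p1.mean_curve, p2.mean_curve)

    def test_different_seeds_agree_on_the_mode(self):
        d = _step_series(seed=12)
        modes = {
            int(np.argmax(run_changepoint(d, mcmc=FAST, seed=s).k_posterior))
            for s in (13, 14, 15)
        }
        assert modes == {1}

    def test_translation_invariance_of_mean_curve(self):
        d = _step_series(seed=16)
        shifted = SeriesData(d.t, d.y + 100.0)
        p1 = run_changepoint(d, mcmc=FAST, seed=17)
        p2 = run_changepoint(shifted, mcmc=FAST, seed=17)
        assert np.allclose(p2.mean_curve, p1.mean_curve + 100.0, atol=1e-9)

    def test_k_max_must_be_below_n(self):
        d = SeriesData(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            run_changepoint(d, ChangepointPriors(k_max=10))


class TestMeanCurve:
    def test_flat_data_curve_is_near_the_shrunk_mean(self):
        rng = np.random.default_rng(18)
        y = rng.normal(5.0, 0.1, 50)
        post = run_changepoint(SeriesData(np.arange(50.0), y), mcmc=FAST, seed=19)
        assert np.allclose(post.mean_curve, y.mean(), atol=0.1)

    def test_step_truth_within_credible_band(self):
        d = _step_series(seed=20)
        post = run_changepoint(d, mcmc=FAST, seed=21)
        truth = np.where(d.t < 50, 0.0, 1.0)
        inside = (truth >= post.ci_low - 1e-9) & (truth <= post.ci_high + 1e-9)
        assert inside.mean() >= 0.95

    def test_band_width_shrinks_with_sample_size(self):
        widths = []
        for n in (50, 200):
            d = _step_series(n=n, switch=n // 2, sigma=0.2, seed=22)
            post = run_changepoint(d, mcmc=FAST, seed=23)
            widths.append(float(np.median(post.ci_high - post.ci_low)))
        assert widths[1] < widths[0]

    def test_posterior_mean_curve_on_custom_grid_matches(self):
        d = _step_series(seed=24)
        post = run_changepoint(d, mcmc=FAST, seed=25)
        mean, lo, hi = posterior_mean_curve(post, d.t)
        assert np.allclose(mean, post.mean_curve)
        assert np.allclose(lo, post.ci_low)
        assert np.allclose(hi, post.ci_high)


def test_series_data_accepts_descending_axis():
    d = SeriesData(np.array([5.0, 4.0, 3.0, 2.0]), np.array([1.0, 2.0, 3.0, 4.0]))
    assert np.all(np.diff(d.t) > 0)
    assert d.y[0] == 4.0


def test_series_data_validation():
    with pytest.raises(ValueError):
        SeriesData(np.array([0.0, 1.0, 1.0, 2.0]), np.zeros(4))
    with pytest.raises(ValueError):
        SeriesData(np.array([0.0, 1.0, 2.0]), np.zeros(3))
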