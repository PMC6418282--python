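import numpy as np
import pytest
from scipy import stats
from scipy.integrate import simpson

from gensmr.geometry import StateSpace
from gensmr.model import (
    Parameters,
    halfnormal_rate,
    hazard_to_prob,
    inclusion_logprior,
    marking_loglik,
    resighting_loglik,
    sex_logprior,
    telemetry_loglik,
    transience_logdensity,
)


class TestDetectionFunctions:
    @pytest.mark.parametrize(
        "d, lam0, sigma, expected",
        [
            (0.0, 0.05, 5.0, 0.05),
            (5.0, 0.05, 5.0, 0.05 * np.exp(-0.5)),  # d = sigma
            (1.0, 0.0, 2.0, 0.0),
        ],
    )
    def test_halfnormal_values(self, d, lam0, sigma, expected):
        assert halfnormal_rate(d, lam0, sigma) == pytest.approx(expected)

    def test_far_tail_negligible(self):
        assert halfnormal_rate(10 * 3.0, 0.05, 3.0) < 1e-21 * 0.05

    def test_monotone_in_distance(self):
        d = np.linspace(0, 30, 100)
        r = halfnormal_rate(d, 0.1, 4.0)
        assert np.all(np.diff(r) <= 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            halfnormal_rate(-1.0, 0.05, 5.0)

    @pytest.mark.parametrize(
        "rate, expected",
        [(0.0, 0.0), (0.05, 1 - np.exp(-0.05)), (1e6, 1.0)],
    )
    def test_hazard_to_prob(self, rate, expected):
        assert hazard_to_prob(rate) == pytest.approx(expected)


class TestMarkingLoglik:
    def test_zero_rate_zero_counts(self):
        params = Parameters(lam0_m=0.0, lam0_r=0.1, sigma_d=2.0)
        ll = marking_loglik(
            np.zeros((2, 1)), [[0.0, 0.0], [1.0, 1.0]], params,
            np.full((2, 1), 5.0), [[0.0, 0.0]],
        )
        assert ll == pytest.approx(0.0)

    def test_single_capture_at_zero_distance(self):
        params = Parameters(lam0_m=0.05, lam0_r=0.1, sigma_d=2.0)
        ll = marking_loglik([[1]], [[0.0, 0.0]], params, [[1.0]], [[0.0, 0.0]])
        assert ll == pytest.approx(np.log(1 - np.exp(-0.05)))

    def test_matches_scipy_binomial_oracle(self, rng):
        """Brute-force oracle: the same sum assembled from scipy binomial
        log-pmfs, looping over individuals and traps."""
        n, J = 5, 3
        s = rng.uniform(0, 10, (n, 2))
        traps = rng.uniform(0, 10, (J, 2))
        E = rng.integers(1, 8, (n, J)).astype(float)
        params = Parameters(lam0_m=0.2, lam0_r=0.1, sigma_d=3.0)
        p = np.empty((n, J))
        for i in range(n):
            for j in range(J):
                d = np.linalg.norm(s[i] - traps[j])
                p[i, j] = 1 - np.exp(-0.2 * np.exp(-(d**2) / (2 * 3.0**2)))
        y = rng.binomial(E.astype(int), p).astype(float)
        expected = stats.binom.logpmf(y, E, p).sum()
        assert marking_loglik(y, s, params, E, traps) == pytest.approx(expected)

    def test_counts_above_exposure_rejected(self):
        params = Parameters(lam0_m=0.1, lam0_r=0.1, sigma_d=2.0)
        with pytest.raises(ValueError):
            marking_loglik([[3]], [[0.0, 0.0]], params, [[2.0]], [[0.0, 0.0]])


class TestResightingLoglik:
    def test_impossible_count_is_minus_inf(self):
        params = Parameters(lam0_r=0.0, sigma_d=2.0)
        ll = resighting_loglik([[1]], [[0.0, 0.0]], None, params, [[17.0]], [[0.0, 0.0]])
        assert ll == -np.inf

    def test_closed_form_single_cell(self):
        """One individual at distance giving rate 0.1, E = 17, count 2:
        Poisson(1.7) log-pmf at 2."""
        params = Parameters(lam0_r=0.1, sigma_d=2.0)
        ll = resighting_loglik([[2]], [[0.0, 0.0]], None, params, [[17.0]], [[0.0, 0.0]])
        assert ll == pytest.approx(stats.poisson.logpmf(2, 1.7))

    def test_matches_scipy_poisson_oracle(self, rng):
        n, J = 6, 4
        s = rng.uniform(0, 12, (n, 2))
        traps = rng.uniform(0, 12, (J, 2))
        E = rng.integers(1, 18, (n, J)).astype(float)
        params = Parameters(lam0_r=0.3, sigma_d=2.5)
        mu = np.empty((n, J))
        for i in range(n):
            for j in range(J):
                d = np.linalg.norm(s[i] - traps[j])
                mu[i, j] = E[i, j] * 0.3 * np.exp(-(d**2) / (2 * 2.5**2))
        y = rng.poisson(mu)
        expected = stats.poisson.logpmf(y, mu).sum()
        got = resighting_loglik(y, s, None, params, E, traps)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_sex_specific_equal_params_match_pooled(self, rng):
        """With identical male/female parameters the sex-specific likelihood
        reproduces the pooled one exactly."""
        n, J = 5, 3
        s = rng.uniform(0, 10, (n, 2))
        traps = rng.uniform(0, 10, (J, 2))
        E = np.full((n, J), 17.0)
        y = rng.poisson(0.5, (n, J))
        sex = rng.integers(0, 2, n)
        pooled = Parameters(lam0_r=0.2, sigma_d=3.0)
        paired = Parameters(lam0_r=(0.2, 0.2), sigma_d=(3.0, 3.0))
        assert resighting_loglik(y, s, sex, paired, E, traps) == pytest.approx(
            resighting_loglik(y, s, None, pooled, E, traps)
        )

    def test_negative_counts_rejected(self):
        params = Parameters(lam0_r=0.1, sigma_d=2.0)
        with pytest.raises(ValueError):
            resighting_loglik([[-1]], [[0.0, 0.0]], None, params, [[17.0]], [[0.0, 0.0]])


class TestTelemetryLoglik:
    def test_density_at_center(self):
        sigma = 2.5
        ll = telemetry_loglik([np.array([[1.0, 2.0]])], [[1.0, 2.0]], sigma)
        assert ll == pytest.approx(-np.log(2 * np.pi * sigma**2))

    def test_doubling_sigma_at_center(self):
        at = [np.array([[0.0, 0.0]])]
        l1 = telemetry_loglik(at, [[0.0, 0.0]], 1.0)
        l2 = telemetry_loglik(at, [[0.0, 0.0]], 2.0)
        assert l1 - l2 == pytest.approx(2 * np.log(2))

    def test_profile_maximized_near_generating_sigma(self, rng):
        sigma = 3.0
        locs = [rng.normal(0.0, sigma, (400, 2))]
        grid = np.linspace(1.5, 5.0, 71)
        lls = [telemetry_loglik(locs, [[0.0, 0.0]], s) for s in grid]
        assert abs(grid[int(np.argmax(lls))] - sigma) < 0.3

    def test_matches_scipy_normal_oracle(self, rng):
        locs = [rng.normal(0, 1, (7, 2)), rng.normal(2, 1, (3, 2))]
        s = np.array([[0.3, -0.2], [1.8, 2.1]])
        expected = sum(
            stats.norm.logpdf(l, loc=s[i], scale=1.7).sum()
            for i, l in enumerate(locs)
        )
        assert telemetry_loglik(locs, s, 1.7) == pytest.approx(expected)


class TestTransienceDensity:
    ss = StateSpace(0.0, 100.0, 0.0, 80.0)

    def test_negligible_truncation_at_center(self):
        s_m = [[50.0, 40.0]]
        ld = transience_logdensity([[51.0, 41.0]], s_m, 2.0, self.ss)
        untrunc = stats.norm.logpdf(1.0, 0, 2.0) * 2 - 0  # two axes, unit shifts
        assert ld == pytest.approx(
            stats.norm.logpdf(51, 50, 2) + stats.norm.logpdf(41, 40, 2), abs=1e-6
        )

    def test_corner_truncation_mass_quarter(self):
        """Centered exactly at a corner, the kernel keeps 1/4 of its mass."""
        ld_corner = transience_logdensity([[0.5, 0.5]], [[0.0, 0.0]], 1.0, self.ss)
        ld_center = transience_logdensity([[50.5, 40.5]], [[50.0, 40.0]], 1.0, self.ss)
        assert ld_corner - ld_center == pytest.approx(np.log(4.0), abs=1e-9)

    def test_outside_rectangle_minus_inf(self):
        assert transience_logdensity([[-1.0, 5.0]], [[5.0, 5.0]], 3.0, self.ss) == -np.inf

    @pytest.mark.parametrize("center", [(50.0, 40.0), (3.0, 2.0), (99.0, 79.0)])
    def test_quadrature_normalization(self, center):
        """The truncated kernel integrates to 1 over the rectangle (Simpson
        quadrature oracle), including near edges and corners."""
        sigma_t = 9.0
        xs = np.linspace(self.ss.xmin, self.ss.xmax, 401)
        ys = np.linspace(self.ss.ymin, self.ss.ymax, 321)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel()])
        ld = transience_logdensity(
            pts, np.tile(center, (len(pts), 1)), sigma_t, self.ss, total=False
        )
        dens = np.exp(ld).reshape(X.shape)
        integral = simpson(simpson(dens, x=ys, axis=1), x=xs)
        assert integral == pytest.approx(1.0, abs=1e-4)


class TestPriors:
    def test_sex_logprior_half(self):
        assert sex_logprior(np.zeros(10), 0.5) == pytest.approx(-10 * np.log(2))

    def test_sex_logprior_impossible(self):
        assert sex_logprior(np.array([0, 1]), 1.0) == -np.inf

    def test_priors_match_bernoulli_products(self, rng):
        sex = rng.integers(0, 2, 30)
        z = rng.integers(0, 2, 30)
        assert sex_logprior(sex, 0.33) == pytest.approx(
            stats.bernoulli.logpmf(sex, 0.33).sum()
        )
        assert inclusion_logprior(z, 0.7) == pytest.approx(
            stats.bernoulli.logpmf(z, 0.7).sum()
        )


class TestParameters:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            Parameters(lam0_r=-0.1)
        with pytest.raises(ValueError):
            Parameters(sigma_d=0.0)
        with pytest.raises(ValueError):
            Parameters(psi=1.0)

    def test_sex_pair_normalization(self):
        p = Parameters(lam0_r=(0.1, 0.2), sigma_d=3.0)
        assert p.sex_specific
        np.testing.assert_allclose(p.lam0_r_pair, [0.1, 0.2])
        np.testing.assert_allclose(p.sigma_d_pair, [3.0, 3.0])
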