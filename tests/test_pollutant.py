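"""Latent-concentration component: likelihood pieces vs brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from airh2m.io import CovariatePanel
from airh2m.pollutant import (ar_residual_loglik, backtransform_mu,
                              measurement_loglik, pollutant_mean)


def _covs(rng, T):
    return CovariatePanel(
        temperature=rng.normal(10, 5, T),
        rel_humidity=rng.uniform(50, 95, T),
        holiday_indicator=np.zeros(T, bool),
        time_index=np.arange(1, T + 1, dtype=float),
    )


class TestPollutantMean:
    def test_zero_parameters_give_zero(self, rng):
        T, P = 8, 3
        mu = pollutant_mean(np.zeros((P, 5)), _covs(rng, T), np.zeros((T, P)))
        assert np.all(mu == 0)

    def test_intercept_only(self, rng):
        T, P = 8, 2
        gamma = np.zeros((P, 5))
        gamma[:, 0] = [1.0, -2.0]
        mu = pollutant_mean(gamma, _covs(rng, T), np.zeros((T, P)))
        np.testing.assert_allclose(mu[:, 0], 1.0)
        np.testing.assert_allclose(mu[:, 1], -2.0)

    def test_matches_scalar_double_loop_oracle(self, rng):
        T, P = 7, 4
        cov = _covs(rng, T)
        gamma = rng.normal(0, 0.5, (P, 5))
        theta = rng.normal(0, 1, (T, P))
        got = pollutant_mean(gamma, cov, theta)
        want = np.empty((T, P))
        for t in range(T):
            for p in range(P):
                want[t, p] = (gamma[p, 0]
                              + gamma[p, 1] * cov.temperature[t]
                              + gamma[p, 2] * cov.temperature[t] ** 2
                              + gamma[p, 3] * cov.rel_humidity[t]
                              + gamma[p, 4] * cov.rel_humidity[t] ** 2
                              + theta[t, p])
        np.testing.assert_allclose(got, want, atol=1e-12, rtol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pollutant_mean(np.zeros((2, 5)), _covs(rng, 5), np.zeros((4, 2)))


class TestMeasurementLoglik:
    def test_single_cell_closed_form(self):
        ll = measurement_loglik(np.array([[1.3]]), np.array([[True]]),
                                np.array([[1.3]]), np.array([1.0]))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_masking_removes_exactly_that_term(self, rng):
        T, P = 5, 2
        Y = rng.normal(0, 1, (T, P))
        mu = rng.normal(0, 1, (T, P))
        sig = np.array([0.7, 1.4])
        full_mask = np.ones((T, P), bool)
        ll_full = measurement_loglik(Y, full_mask, mu, sig)
        drop = full_mask.copy()
        drop[3, 1] = False
        ll_drop = measurement_loglik(Y, drop, mu, sig)
        term = norm.logpdf(Y[3, 1], mu[3, 1], sig[1])
        assert ll_full - ll_drop == pytest.approx(term, rel=1e-12)

    def test_matches_per_cell_oracle(self, rng):
        T, P = 3, 2
        Y = rng.normal(0, 1, (T, P))
        mu = rng.normal(0, 1, (T, P))
        mask = rng.uniform(size=(T, P)) > 0.3
        sig = np.array([0.5, 2.0])
        want = sum(norm.logpdf(Y[t, p], mu[t, p], sig[p])
                   for t in range(T) for p in range(P) if mask[t, p])
        got = measurement_loglik(Y, mask, mu, sig)
        assert got == pytest.approx(want, abs=1e-12)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            measurement_loglik(np.zeros((2, 1)), np.ones((2, 1), bool),
                               np.zeros((2, 1)), np.array([0.0]))


class TestARResidualLoglik:
    def test_constant_theta_identity_cov(self):
        T, P = 6, 3
        theta = np.tile([0.3, -0.1, 2.0], (T, 1))
        ll = ar_residual_loglik(theta, np.eye(P), lag=1, include_init=False)
        assert ll == pytest.approx((T - 1) * (-P / 2 * np.log(2 * np.pi)))

    def test_univariate_reduces_to_scalar_oracle(self, rng):
        T = 9
        theta = rng.normal(0, 1, (T, 1))
        s2 = 0.4
        got = ar_residual_loglik(theta, np.array([[s2]]), lag=1,
                                 include_init=False)
        want = sum(norm.logpdf(theta[t, 0], theta[t - 1, 0], np.sqrt(s2))
                   for t in range(1, T))
        assert got == pytest.approx(want, rel=1e-12)

    def test_pollutant_relabeling_symmetry(self, rng):
        T, P = 8, 4
        theta = rng.normal(0, 1, (T, P))
        A = rng.normal(0, 1, (P, P))
        Sigma = A @ A.T + P * np.eye(P)
        perm = rng.permutation(P)
        ll = ar_residual_loglik(theta, Sigma)
        ll_perm = ar_residual_loglik(theta[:, perm], Sigma[np.ix_(perm, perm)])
        assert ll_perm == pytest.approx(ll, rel=1e-12)

    def test_lag2_pairs_rows_two_apart(self, rng):
        T = 7
        theta = rng.normal(0, 1, (T, 1))
        got = ar_residual_loglik(theta, np.array([[1.0]]), lag=2,
                                 include_init=False)
        want = sum(norm.logpdf(theta[t, 0], theta[t - 2, 0], 1.0)
                   for t in range(2, T))
        assert got == pytest.approx(want, rel=1e-12)

    def test_non_spd_covariance_rejected(self, rng):
        theta = rng.normal(0, 1, (5, 2))
        with pytest.raises(ValueError):
            ar_residual_loglik(theta, np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_joint_density_decomposes(self, rng):
        """measurement + AR + init terms = monolithic small-instance density."""
        T, P = 4, 2
        theta = rng.normal(0, 1, (T, P))
        Y = theta + rng.normal(0, 0.3, (T, P))
        mask = np.ones((T, P), bool)
        sig = np.array([0.3, 0.3])
        Sigma = np.array([[1.0, 0.4], [0.4, 1.0]])
        joint = (measurement_loglik(Y, mask, theta, sig)
                 + ar_residual_loglik(theta, Sigma, lag=1, init_sd=10.0))
        # monolithic oracle: every factor written out explicitly
        want = 0.0
        for t in range(T):
            for p in range(P):
                want += norm.logpdf(Y[t, p], theta[t, p], sig[p])
        for t in range(1, T):
            want += multivariate_normal.logpdf(theta[t], theta[t - 1], Sigma)
        want += norm.logpdf(theta[0], 0, 10.0).sum()
        assert joint == pytest.approx(want, rel=1e-12)

    def test_diagonal_cov_decouples_pollutants(self, rng):
        T, P = 6, 3
        theta = rng.normal(0, 1, (T, P))
        s2 = np.array([0.5, 1.0, 2.0])
        joint = ar_residual_loglik(theta, np.diag(s2), include_init=False)
        per_pollutant = sum(
            ar_residual_loglik(theta[:, [p]], np.array([[s2[p]]]),
                               include_init=False)
            for p in range(P))
        assert joint == pytest.approx(per_pollutant, rel=1e-12)


class TestBacktransform:
    def test_examples(self, small_panel):
        from airh2m.io import standardize
        std = standardize(small_panel)
        T, P = std.values.shape
        zero = backtransform_mu(np.zeros((T, P)), std)
        np.testing.assert_allclose(zero, np.tile(std.center, (T, 1)))
        obs = std.observed_mask
        back = backtransform_mu(np.nan_to_num(std.values), std)
        np.testing.assert_allclose(back[obs], small_panel.values[obs], rtol=1e-12)

    def test_arithmetic(self, small_panel):
        from dataclasses import replace
        panel = replace(small_panel, center=np.array([10.0, 0.0, 0.0]),
                        scale=np.array([2.0, 1.0, 1.0]))
        out = backtransform_mu(np.full((1, 3), 1.5), panel)
        assert out[0, 0] == pytest.approx(13.0)

    def test_requires_parameters(self, small_panel):
        with pytest.raises(ValueError):
            backtransform_mu(np.zeros((10, 3)), small_panel)
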