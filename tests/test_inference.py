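"""Inference engine: priors, sampler kernels, estimator contracts."""

import numpy as np
import pandas as pd
import pytest

from airh2m.estimators import (JointHierarchicalModel, PluginPoissonModel,
                               StudyData, TwoStageModel)
from airh2m.gibbs import ModelData, update_theta
from airh2m.io import OutcomePanel, PollutantPanel
from airh2m.priors import (MCMCConfig, PriorConfig, default_iw_scale,
                           prior_relative_rate_range)


class TestDefaultIWScale:
    def test_uncorrelated_columns_give_scaled_identity(self):
        # exactly orthogonal +-1 patterns -> empirical correlation = I
        vals = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], float)
        panel = _panel(vals)
        D = default_iw_scale(panel, d=2)
        np.testing.assert_allclose(D, 2 * np.eye(2), atol=1e-12)

    def test_duplicated_column_triggers_spd_nudge(self, rng):
        x = rng.normal(size=50)
        panel = _panel(np.column_stack([x, x, rng.normal(size=50)]))
        D = default_iw_scale(panel, d=3)
        assert np.linalg.eigvalsh(D).min() > 0
        np.testing.assert_allclose(np.diag(D), 3.0, rtol=1e-6)

    def test_pairwise_complete_cells_only(self, rng):
        vals = rng.normal(size=(60, 2))
        vals[:, 1] = vals[:, 0] + 0.1 * rng.normal(size=60)
        mask = np.ones((60, 2), bool)
        mask[:10, 0] = False
        panel = PollutantPanel(
            dates=pd.date_range("2011-01-01", periods=60, freq="D"),
            values=np.where(mask, vals, np.nan), observed_mask=mask,
            names=["a", "b"])
        D = default_iw_scale(panel, d=2)
        both = mask.all(axis=1)
        want = np.corrcoef(vals[both, 0], vals[both, 1])[0, 1]
        assert D[0, 1] == pytest.approx(2 * want, rel=1e-9)

    def test_single_pollutant_rejected(self, rng):
        with pytest.raises(ValueError):
            default_iw_scale(_panel(rng.normal(size=(20, 1))), d=1)


def test_informative_beta_prior_relative_rate_range():
    lo, hi = prior_relative_rate_range(0.1)
    assert (round(lo, 2), round(hi, 2)) == (0.82, 1.22)


def test_sensitivity_variant_expressible_through_config():
    sens = PriorConfig.sensitivity()
    assert sens.coef_sd == pytest.approx(np.sqrt(1e6))
    assert sens.variance_prior == "invgamma"
    assert (sens.invgamma_a, sens.invgamma_b) == (1.0, 0.001)
    assert (sens.spline_gamma_a, sens.spline_gamma_b) == (0.001, 0.001)
    assert sens.beta_sd == 0.1  # the informative health prior is kept


class TestThetaKernelExactness:
    """The latent-row Gibbs kernel against the exact Gaussian posterior.

    Without an outcome the full conditional is Gaussian and the sweep is an
    exact Gibbs sampler; its stationary distribution must match the
    analytically assembled joint posterior of the latent field.
    """

    def test_matches_dense_precision_oracle(self, rng):
        T, P = 20, 2
        Sigma = np.array([[1.0, 0.5], [0.5, 1.2]])
        sigma2 = np.array([0.3, 0.5])
        truth = np.cumsum(rng.normal(0, 0.5, (T, P)), axis=0)
        Y = truth + rng.normal(0, np.sqrt(sigma2), (T, P))
        mask = np.ones((T, P), bool)
        mask[5, 0] = mask[12, 1] = False
        Y = np.where(mask, Y, np.nan)
        priors = PriorConfig().resolved(P)
        s0 = priors.theta_init_sd**2

        # dense precision of vec(theta) (time-major), exact posterior
        Siginv = np.linalg.inv(Sigma)
        Q = np.zeros((T * P, T * P))
        b = np.zeros(T * P)
        Q[:P, :P] += np.eye(P) / s0
        for t in range(1, T):
            s, sp = slice(t * P, t * P + P), slice((t - 1) * P, t * P)
            Q[s, s] += Siginv
            Q[sp, sp] += Siginv
            Q[s, sp] -= Siginv
            Q[sp, s] -= Siginv
        for t in range(T):
            for p in range(P):
                if mask[t, p]:
                    Q[t * P + p, t * P + p] += 1 / sigma2[p]
                    b[t * P + p] += Y[t, p] / sigma2[p]
        mean_exact = np.linalg.solve(Q, b).reshape(T, P)
        var_exact = np.diag(np.linalg.inv(Q)).reshape(T, P)

        md = ModelData(Y=Y, mask=mask, center=np.zeros(P), scale=np.ones(P))
        theta = np.zeros((T, P))
        kept = []
        m = np.zeros((T, P))
        for it in range(5500):
            update_theta(theta, md, m, Siginv, sigma2, np.zeros(P),
                         np.zeros(T), priors, rng, use_outcome=False)
            if it >= 500:
                kept.append(theta.copy())
        kept = np.asarray(kept)
        np.testing.assert_allclose(kept.mean(axis=0), mean_exact, atol=0.06)
        np.testing.assert_allclose(kept.var(axis=0), var_exact, rtol=0.35)


class TestEstimatorContracts:
    def test_cut_model_stage1_ignores_outcome(self, rng):
        """Stage-1 latent posterior is draw-identical with or without counts."""
        data = _sim_data(rng, T=80, P=2, seed=3)
        mcmc = MCMCConfig(n_burn=200, n_keep=200, n_chains=1, seed=17)
        h2m = TwoStageModel(mcmc=mcmc, health_lag=0, use_confounders=False,
                            standardize=False).fit(data)
        no_outcome = StudyData(data.pollutants, None, None)
        pol_only = JointHierarchicalModel(mcmc=mcmc, health_lag=0,
                                          use_confounders=False,
                                          standardize=False).fit(no_outcome)
        np.testing.assert_array_equal(h2m.mu_mean_, pol_only.mu_mean_)

    def test_me_complete_case_rule(self, rng):
        data = _sim_data(rng, T=60, P=2, seed=4)
        vals = data.pollutants.values.copy()
        mask = data.pollutants.observed_mask.copy()
        mask[30, 0] = False
        vals[30, 0] = np.nan
        panel = PollutantPanel(dates=data.pollutants.dates, values=vals,
                               observed_mask=mask, names=data.pollutants.names)
        m = PluginPoissonModel(mcmc=MCMCConfig(n_burn=50, n_keep=50,
                                               n_chains=1, seed=1),
                               health_lag=1, use_confounders=False,
                               standardize=False)
        m.fit(StudyData(panel, None, data.outcome))
        # day 31 needs the day-30 concentration, which is missing
        assert 31 not in m.rows_used_
        assert 30 in m.rows_used_

    def test_beta_prior_recovery_without_counts(self, rng):
        """No outcome information: beta returns its N(0, 0.1 sd) prior."""
        data = _sim_data(rng, T=60, P=2, seed=5)
        m = PluginPoissonModel(mcmc=MCMCConfig(n_burn=0, n_keep=8000,
                                               n_chains=1, seed=2),
                               health_lag=0, use_confounders=False,
                               standardize=False)
        m.fit(StudyData(data.pollutants, None, None))
        beta = m.posterior_.get("beta")
        se = 0.1 / np.sqrt(beta.shape[0])
        assert np.all(np.abs(beta.mean(axis=0)) < 4 * se)
        np.testing.assert_allclose(beta.std(axis=0), 0.1, rtol=0.06)

    def test_plugin_and_joint_agree_without_measurement_noise(self, rng):
        """With error-free measurements the two posteriors coincide (MC error)."""
        data = _sim_data(rng, T=150, P=2, seed=6, meas_var=1e-8)
        mcmc = MCMCConfig(n_burn=800, n_keep=1200, n_chains=1, seed=8)
        kw = dict(health_lag=0, use_confounders=False, standardize=False)
        me = PluginPoissonModel(mcmc=mcmc, **kw).fit(data)
        jm = JointHierarchicalModel(mcmc=mcmc, **kw).fit(data)
        sm, sj = me.posterior_.summary("beta"), jm.posterior_.summary("beta")
        tol = 3.0 * np.sqrt(sm["sd"] ** 2 + sj["sd"] ** 2) / np.sqrt(50)
        assert np.all(np.abs(sm["mean"] - sj["mean"]).values
                      < np.maximum(tol, 0.01))

    def test_degenerate_stage1_makes_cut_model_coincide_with_plugin(self, rng):
        data = _sim_data(rng, T=150, P=2, seed=7, meas_var=1e-8)
        mcmc = MCMCConfig(n_burn=800, n_keep=1200, n_chains=1, seed=9)
        kw = dict(health_lag=0, use_confounders=False, standardize=False)
        me = PluginPoissonModel(mcmc=mcmc, **kw).fit(data)
        h2m = TwoStageModel(mcmc=mcmc, **kw).fit(data)
        sm, sh = me.posterior_.summary("beta"), h2m.posterior_.summary("beta")
        tol = 3.0 * np.sqrt(sm["sd"] ** 2 + sh["sd"] ** 2) / np.sqrt(50)
        assert np.all(np.abs(sm["mean"] - sh["mean"]).values
                      < np.maximum(tol, 0.01))


def _panel(values):
    T, P = values.shape
    return PollutantPanel(
        dates=pd.date_range("2011-01-01", periods=T, freq="D"),
        values=values, observed_mask=np.isfinite(values),
        names=[f"p{i}" for i in range(P)])


def _sim_data(rng, T, P, seed, meas_var=0.1):
    from airh2m.simulate import SimulationConfig, simulate_dataset
    corr = np.eye(P) * 0.3 + 0.7 * np.ones((P, P))
    np.fill_diagonal(corr, 1.0)
    beta = np.array([0.2, -0.2] + [0.0] * (P - 2))[:P]
    cfg = SimulationConfig(n_days=T, n_pollutants=P, corr=corr,
                           beta_true=beta, meas_var=meas_var, seed=seed)
    data, _ = simulate_dataset(cfg, 0)
    return data
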