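"""The three estimation strategies, as sklearn-style estimator classes.

* :class:`PluginPoissonModel` ("ME"): the conventional benchmark — measured
  concentrations plugged straight into the Poisson health model, complete
  cases only.  Measurement error is ignored.
* :class:`TwoStageModel` ("H2M"): the pollutant component is fitted alone;
  its posterior for the latent concentrations is then fed forward into the
  health component, one first-stage draw per second-stage iteration, so
  exposure uncertainty propagates but the outcome never feeds back (a "cut"
  model).
* :class:`JointHierarchicalModel` ("H2Mjoint"): both components estimated
  jointly; exposure uncertainty feeds forward and outcome information feeds
  back into the latent concentrations.

All three share the init-params / ``fit`` / trailing-underscore conventions
of scikit-learn estimators and a common panel-triple input.  The
module-level ``fit_me`` / ``fit_h2m`` / ``fit_h2mjoint`` functions are thin
wrappers returning the posterior directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import io as tio
from .gibbs import ModelData, make_layout, run_glm_chain, run_joint_chain
from .health import DEFAULT_KNOTS, spline_basis, spline_knots
from .diagnostics import dic as _dic
from .priors import MCMCConfig, PriorConfig
from .samples import PosteriorSamples

__all__ = [
    "StudyData",
    "PluginPoissonModel",
    "TwoStageModel",
    "JointHierarchicalModel",
    "fit_me",
    "fit_h2m",
    "fit_h2mjoint",
]


@dataclass
class StudyData:
    """The aligned panel triple a fit consumes."""

    pollutants: tio.PollutantPanel
    covariates: tio.CovariatePanel | None = None
    outcome: tio.OutcomePanel | None = None

    def subset(self, names: list[str]) -> "StudyData":
        """Restrict to a subset of pollutants (single-pollutant runs)."""
        p = self.pollutants
        idx = [p.names.index(n) for n in names]
        sub = tio.PollutantPanel(
            dates=p.dates, values=p.values[:, idx],
            observed_mask=p.observed_mask[:, idx],
            names=[p.names[i] for i in idx],
            units=[p.units[i] for i in idx],
            center=None if p.center is None else p.center[idx],
            scale=None if p.scale is None else p.scale[idx],
        )
        return StudyData(sub, self.covariates, self.outcome)


class _BaseFit(BaseEstimator):
    """Shared data preparation and posterior assembly."""

    def __init__(self, priors=None, mcmc=None, health_lag=1, pollutant_lag=1,
                 knots=None, overdispersion=True, use_confounders=True,
                 standardize=True, prior_only=False):
        self.priors = priors
        self.mcmc = mcmc
        self.health_lag = health_lag
        self.pollutant_lag = pollutant_lag
        self.knots = knots
        self.overdispersion = overdispersion
        self.use_confounders = use_confounders
        self.standardize = standardize
        self.prior_only = prior_only

    # -- data prep ---------------------------------------------------------
    def _resolve(self, data: StudyData):
        priors = self.priors if self.priors is not None else PriorConfig()
        mcmc = self.mcmc if self.mcmc is not None else MCMCConfig()
        panel = data.pollutants
        if self.standardize and panel.center is None:
            panel = tio.standardize(panel)
        P = panel.n_pollutants
        priors = priors.resolved(P, panel if P >= 2 else None)
        center = panel.center if panel.center is not None else np.zeros(P)
        scale = panel.scale if panel.scale is not None else np.ones(P)

        cov = data.covariates if self.use_confounders else None
        Xc = None
        holiday = None
        bases: dict[str, np.ndarray] = {}
        if cov is not None:
            from .pollutant import covariate_design
            Xc = covariate_design(cov)
            holiday = cov.holiday_indicator.astype(float)
            kn = {**DEFAULT_KNOTS, **(self.knots or {})}
            series = {"time": cov.time_index, "temperature": cov.temperature,
                      "rel_humidity": cov.rel_humidity}
            for name, x in series.items():
                knots = spline_knots(x, kn[name])
                bases[name] = spline_basis(x, knots, center=True)
            self.knots_ = {name: spline_knots(series[name], kn[name])
                           for name in series}

        counts = None
        E = 1.0
        if data.outcome is not None:
            counts = data.outcome.counts
            E = data.outcome.expected

        md = ModelData(
            Y=panel.values, mask=panel.observed_mask, center=center,
            scale=scale, counts=counts, E=E, health_lag=self.health_lag,
            Xc=Xc, holiday=holiday, spline_bases=bases,
            overdispersion=self.overdispersion, lag=self.pollutant_lag,
        )
        return md, priors, mcmc, panel

    def _assemble(self, chain_results, priors, mcmc, estimator_name):
        names = chain_results[0][0].keys()
        draws = {k: np.stack([r[0][k] for r in chain_results]) for k in names}
        extras_list = [r[1] for r in chain_results]
        extras = {}
        for key in extras_list[0]:
            vals = [e[key] for e in extras_list]
            if vals[0] is None:
                extras[key] = None
            elif np.isscalar(vals[0]):
                extras[key] = float(np.mean(vals))
            else:
                extras[key] = np.mean(np.stack(vals), axis=0)
        meta = {
            "estimator": estimator_name,
            "priors": priors,
            "mcmc": mcmc,
            "health_lag": self.health_lag,
        }
        post = PosteriorSamples(draws=draws, meta=meta, extras=extras)
        dev = post.get("deviance")
        if np.all(np.isfinite(dev)) and extras.get("eta_mean") is not None:
            from .gibbs import _deviance
            d_at_mean = _deviance(self._O_eff, extras["eta_mean"], self._E)
            self.dic_, self.pd_ = _dic(dev, d_at_mean)
        else:
            self.dic_ = self.pd_ = np.nan
        self.posterior_ = post
        self.diagnostics_ = post.diagnostics() if mcmc.n_chains >= 2 else None
        return post

    def _chain_rngs(self, mcmc):
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)]


class JointHierarchicalModel(_BaseFit):
    """Jointly estimated two-component hierarchical model (H2Mjoint)."""

    def fit(self, data: StudyData, y=None):
        md, priors, mcmc, panel = self._resolve(data)
        if md.counts is not None and md.T <= max(md.lag, md.health_lag):
            raise ValueError("series shorter than the model lags")
        self._O_eff = (md.counts[md.health_lag:].astype(float)
                       if md.counts is not None else None)
        self._E = md.E
        results = []
        for rng in self._chain_rngs(mcmc):
            results.append(run_joint_chain(
                md, priors, mcmc.n_burn, mcmc.n_keep, rng,
                use_outcome=md.counts is not None, thin=mcmc.thin,
                prior_only=self.prior_only))
        post = self._assemble(results, priors, mcmc, "h2mjoint")
        self.mu_mean_ = post.extras["mu_mean"]
        self.panel_ = panel
        return self


class TwoStageModel(_BaseFit):
    """Cut model (H2M): pollutant posterior fed forward, no feedback."""

    def fit(self, data: StudyData, y=None):
        md, priors, mcmc, panel = self._resolve(data)
        if data.outcome is None:
            raise ValueError("two-stage fit needs an outcome")
        self._O_eff = md.counts[md.health_lag:].astype(float)
        self._E = md.E
        L = md.health_lag
        rows_u = np.arange(L, md.T)
        results = []
        for rng in self._chain_rngs(mcmc):
            stage1, ex1 = run_joint_chain(
                md, priors, mcmc.n_burn, mcmc.n_keep, rng,
                use_outcome=False, thin=mcmc.thin, record_mu=True)
            mu_draws = ex1["mu_draws"]              # (n_keep, T, P)
            n1 = len(mu_draws)
            orig = md.center[None, None, :] + md.scale[None, None, :] * mu_draws

            def exposure_fn(it, orig=orig, n1=n1):
                mu = orig[it % n1]
                return mu[rows_u - L] if L > 0 else mu

            res2, ex2 = run_glm_chain(md, priors, mcmc.n_burn, mcmc.n_keep,
                                      rng, rows_u, exposure_fn, thin=mcmc.thin)
            res2 = dict(res2)
            res2["sigma_proc"] = stage1["sigma_proc"]
            res2["Sigma_P"] = stage1["Sigma_P"]
            if "gamma" in stage1:
                res2["gamma"] = stage1["gamma"]
            ex2 = dict(ex2)
            ex2["mu_mean"] = ex1["mu_mean"]
            ex2.pop("rows_u", None)
            results.append((res2, ex2))
        post = self._assemble(results, priors, mcmc, "h2m")
        self.mu_mean_ = post.extras["mu_mean"]
        self.panel_ = panel
        return self


class PluginPoissonModel(_BaseFit):
    """Plug-in benchmark (ME): measured concentrations enter directly.

    Days whose (lagged) exposure vector has any missing pollutant are
    dropped (complete-case rule).  With no outcome supplied the health
    coefficients are sampled from their priors, which is the cheap way to
    audit the prior specification.
    """

    def fit(self, data: StudyData, y=None):
        md, priors, mcmc, panel = self._resolve(data)
        P = md.P
        if data.outcome is None or self.prior_only:
            return self._fit_prior(md, priors, mcmc, panel)
        L = md.health_lag
        exp_orig = md.center[None, :] + md.scale[None, :] * np.nan_to_num(md.Y)
        rows_u = np.arange(L, md.T)
        complete = md.mask[rows_u - L].all(axis=1) if L > 0 else md.mask[rows_u].all(axis=1)
        rows_u = rows_u[complete]
        if len(rows_u) == 0:
            raise ValueError("no complete-case days")
        self._O_eff = md.counts[rows_u].astype(float)
        self._E = md.E
        expo = exp_orig[rows_u - L] if L > 0 else exp_orig[rows_u]

        results = []
        for rng in self._chain_rngs(mcmc):
            results.append(run_glm_chain(md, priors, mcmc.n_burn, mcmc.n_keep,
                                         rng, rows_u, lambda it: expo,
                                         thin=mcmc.thin))
        post = self._assemble(results, priors, mcmc, "me")
        self.rows_used_ = rows_u
        self.panel_ = panel
        return self

    def _fit_prior(self, md, priors, mcmc, panel):
        """Direct prior draws for the health-coefficient block."""
        layout = make_layout(md)
        draws = {}
        rngs = self._chain_rngs(mcmc)
        n = mcmc.n_keep
        beta0 = np.stack([r.normal(0, priors.coef_sd, n) for r in rngs])
        beta = np.stack([r.normal(0, priors.beta_sd, (n, md.P)) for r in rngs])
        draws["beta0"], draws["beta"] = beta0, beta
        if layout.has_holiday:
            draws["delta"] = np.stack([r.normal(0, priors.coef_sd, n) for r in rngs])
        draws["deviance"] = np.full((mcmc.n_chains, n), np.nan)
        self.posterior_ = PosteriorSamples(
            draws=draws, meta={"estimator": "me", "priors": priors,
                               "mcmc": mcmc, "prior_only": True})
        self.dic_ = self.pd_ = np.nan
        self.diagnostics_ = None
        self.panel_ = panel
        return self


def _wrap(cls):
    def fitter(data_or_panel, covariates=None, outcome=None,
               priors=None, mcmc=None, **kwargs) -> PosteriorSamples:
        if isinstance(data_or_panel, StudyData):
            data = data_or_panel
        else:
            data = StudyData(data_or_panel, covariates, outcome)
        model = cls(priors=priors, mcmc=mcmc, **kwargs)
        model.fit(data)
        return model.posterior_
    return fitter


fit_me = _wrap(PluginPoissonModel)
fit_h2m = _wrap(TwoStageModel)
fit_h2mjoint = _wrap(JointHierarchicalModel)
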