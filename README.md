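# airh2m — joint Bayesian hierarchical modelling of multi-pollutant health effects

Short-term air-pollution epidemiology regresses daily event counts (deaths,
admissions) on daily ambient concentrations. Because pollutants are highly
correlated and monitor readings are noisy, the standard practice is one
pollutant at a time with the measured series plugged in directly — which
cannot separate the pollutants' effects and is biased by measurement error.

`airh2m` implements a **two-component hierarchical model**, estimated
jointly, for users who want per-pollutant effect estimates from a
multi-pollutant time series:

**Pollutant component** — measured concentration `Y_pt` (pollutant *p*, day
*t*, standardized) is a noisy version of a latent "true" level:

    Y_pt ~ N(mu_pt, sigma_p^2)
    mu_pt = gamma_0p + gamma_1p T_t + gamma_2p T_t^2 + gamma_3p H_t + gamma_4p H_t^2 + theta_pt
    (theta_1t, ..., theta_Pt)' ~ MVN((theta_1,t-l, ..., theta_P,t-l)', Sigma_P)

The latent residuals follow a driftless multivariate random walk whose
innovation covariance `Sigma_P` carries both temporal dependence and the
cross-pollutant correlation; missing measurements drop out of the
likelihood and are bridged by the walk.

**Health component** — daily counts are overdispersed Poisson on the
*latent, back-transformed* concentrations at lag 1:

    O_t ~ Poisson(E * lambda_t)
    log(lambda_t) = beta_0 + sum_p beta_p mu_p,(t-1) + sum_i s(X_ti; psi_i) + delta I_t + eps_t

with low-rank thin-plate spline smoothers `s` for calendar time,
temperature and relative humidity, a workday/holiday shift `delta`, and a
day-level Normal effect `eps_t`. The informative prior `beta_p ~ N(0, 0.1)`
(sd; a 95% relative-rate range of 0.82–1.22) stabilises the fit under
collinearity.

Because the two components are estimated **jointly**, exposure uncertainty
propagates into the health-effect intervals and outcome information feeds
back into the latent concentrations. Two comparison estimators ship
alongside: **ME** (plug-in: measured concentrations used directly,
complete cases) and **H2M** (two-stage "cut": exposure posterior fed
forward, no feedback). Inference is a purpose-built Gibbs-within-Metropolis
sampler (checkerboard latent updates with Laplace proposals, conjugate
inverse-Wishart/variance steps, IWLS-Metropolis for the Poisson block).

## Worked example

Simulate the six-pollutant study design (latent walks with the London
innovation-correlation matrix, measurement variance 0.1, log-rate
`1 + 0.2 mu1 + 0.2 mu2 - 0.2 mu3`, expected count 37) and fit the joint
model and the plug-in benchmark:

```python
import numpy as np
from airh2m import (JointHierarchicalModel, PluginPoissonModel,
                    MCMCConfig, SimulationConfig)
from airh2m.simulate import simulate_dataset

config = SimulationConfig(n_days=250, seed=1)
data, mu_true = simulate_dataset(config, rep=0)

mcmc = MCMCConfig(n_burn=1000, n_keep=1000, n_chains=1, seed=2)
kwargs = dict(mcmc=mcmc, health_lag=0, use_confounders=False, standardize=False)

joint = JointHierarchicalModel(**kwargs).fit(data)
plugin = PluginPoissonModel(**kwargs).fit(data)

print(joint.posterior_.summary("beta")["mean"].round(3).tolist())
print(plugin.posterior_.summary("beta")["mean"].round(3).tolist())
```

Output (truth is `[0.2, 0.2, -0.2, 0, 0, 0]`):

```
[0.175, 0.201, -0.183, 0.009, 0.011, -0.005]
[0.133, 0.162, -0.157, 0.019, 0.048, 0.035]
```

The plug-in estimates are attenuated towards zero on the true effects and
spill bias onto the null coefficients (measurement error plus
collinearity); the joint model recovers the truth within its posterior
uncertainty, because the latent concentrations are de-noised by the walk
and informed back by the outcome.

For real panels, `load_panel` reads a daily CSV/XLSX (date, one column per
pollutant, temperature, rel_humidity, count; blank = missing) and the same
estimators accept the panel triple; `report_effects` turns posterior draws
into percent-increase-per-IQR tables. A CLI wraps the common workflows:

```sh
airh2m fit london.csv --model h2mjoint --burn 50000 --keep 10000 --chains 2
airh2m simstudy --preset desk --estimators me,h2m,h2mjoint --seed 1
airh2m diagnose airh2m_out/samples.csv
```

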