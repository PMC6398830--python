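"""Latent-concentration (pollutant) component.

Measured concentrations are treated as noisy versions of a latent "true"
daily level: Y_pt ~ N(mu_pt, sigma_p^2).  The latent mean decomposes into a
quadratic meteorology regression plus a residual temporal effect theta_pt,
and the theta vectors follow a driftless multivariate random walk whose
innovation covariance Sigma_P carries both the per-pollutant temporal
dependence (diagonal) and the cross-pollutant correlation (off-diagonal).
Missing measurements simply drop out of the measurement likelihood; the
random walk and the cross-correlations bridge the gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io import CovariatePanel, PollutantPanel

__all__ = [
    "LatentPollutantState",
    "pollutant_mean",
    "measurement_loglik",
    "ar_residual_loglik",
    "backtransform_mu",
]

# diffuse sd for the random-walk initialization rows (t <= lag); a proper
# prior keeps the joint density normalizable
THETA_INIT_SD = 10.0


@dataclass
class LatentPollutantState:
    """Parameters and latent states of the pollutant component."""

    mu: np.ndarray          # T x P latent standardized concentration
    theta: np.ndarray       # T x P residual temporal effects
    gamma: np.ndarray       # P x k regression coefficients (k=5: 1, temp, temp^2, rh, rh^2)
    sigma_proc: np.ndarray  # P measurement ("process") sds
    Sigma_P: np.ndarray     # P x P innovation covariance of the walk
    lag: int = 1

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.theta = np.asarray(self.theta, float)
        self.gamma = np.atleast_2d(np.asarray(self.gamma, float))
        self.sigma_proc = np.asarray(self.sigma_proc, float)
        self.Sigma_P = np.atleast_2d(np.asarray(self.Sigma_P, float))
        if np.any(self.sigma_proc <= 0):
            raise ValueError("sigma_proc must be positive")
        if not np.allclose(self.Sigma_P, self.Sigma_P.T):
            raise ValueError("Sigma_P must be symmetric")
        if self.lag < 1:
            raise ValueError("lag must be a positive integer")


def covariate_design(covariates: CovariatePanel) -> np.ndarray:
    """T x 5 design (1, temp, temp^2, rhum, rhum^2) on the measured scale."""
    t = covariates.temperature
    r = covariates.rel_humidity
    return np.column_stack([np.ones_like(t), t, t * t, r, r * r])


def pollutant_mean(gamma: np.ndarray, covariates: CovariatePanel,
                   theta: np.ndarray) -> np.ndarray:
    """Latent mean mu_pt = gamma_0p + quadratic meteorology terms + theta_pt."""
    gamma = np.atleast_2d(np.asarray(gamma, float))
    theta = np.asarray(theta, float)
    X = covariate_design(covariates)
    if gamma.shape[1] != X.shape[1]:
        raise ValueError(f"gamma has {gamma.shape[1]} columns, expected {X.shape[1]}")
    if theta.shape != (X.shape[0], gamma.shape[0]):
        raise ValueError("theta shape does not match (T, P)")
    return X @ gamma.T + theta


def measurement_loglik(Y: np.ndarray, mask: np.ndarray, mu: np.ndarray,
                       sigma_proc: np.ndarray) -> float:
    """Sum of log N(Y_pt | mu_pt, sigma_p^2) over observed cells only.

    Missingness is taken completely at random, so unobserved cells
    contribute nothing.
    """
    sigma_proc = np.asarray(sigma_proc, float)
    if np.any(sigma_proc <= 0):
        raise ValueError("sigma_proc must be positive")
    Y = np.asarray(Y, float)
    mu = np.asarray(mu, float)
    mask = np.asarray(mask, bool)
    ll = norm.logpdf(np.where(mask, Y, 0.0), loc=np.where(mask, mu, 0.0),
                     scale=sigma_proc[None, :])
    return float(np.sum(ll[mask]))


def _mvn_logpdf(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise MVN(0, cov) log density; raises on non-SPD covariance."""
    x = np.atleast_2d(x)
    P = cov.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance matrix is not positive definite") from e
    sol = np.linalg.solve(L, x.T)
    quad = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (P * np.log(2 * np.pi) + logdet + quad)


def ar_residual_loglik(theta: np.ndarray, Sigma_P: np.ndarray, lag: int = 1,
                       init_sd: float = THETA_INIT_SD,
                       include_init: bool = True) -> float:
    """Log density of the lag-l multivariate random walk on theta.

    Rows t = lag+1..T contribute MVN(theta_t | theta_{t-lag}, Sigma_P); the
    first ``lag`` rows receive a diffuse N(0, init_sd^2) initialization
    prior (optional, on by default).
    """
    theta = np.atleast_2d(np.asarray(theta, float))
    Sigma_P = np.atleast_2d(np.asarray(Sigma_P, float))
    T = theta.shape[0]
    if T <= lag:
        raise ValueError("need more rows than the lag")
    diffs = theta[lag:] - theta[:-lag]
    ll = float(np.sum(_mvn_logpdf(diffs, Sigma_P)))
    if include_init:
        ll += float(np.sum(norm.logpdf(theta[:lag], scale=init_sd)))
    return ll


def backtransform_mu(mu_std: np.ndarray, panel: PollutantPanel) -> np.ndarray:
    """Map latent concentrations from the standardized to the original scale.

    The health coefficients multiply original-unit concentrations, so
    reported effects per IQR use the observed-data IQRs directly.
    """
    if panel.center is None or panel.scale is None:
        raise ValueError("panel carries no standardization parameters")
    return np.asarray(mu_std, float) * panel.scale[None, :] + panel.center[None, :]
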