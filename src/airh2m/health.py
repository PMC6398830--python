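"""Poisson time-series health component.

Daily event counts are Poisson with rate E * lambda_t, where log(lambda_t)
combines the (lagged, original-unit) latent pollutant concentrations, smooth
confounder terms for calendar time / temperature / relative humidity, a
workday-vs-holiday shift, and a day-level Normal random effect that absorbs
overdispersion.  The smoothers are low-rank thin-plate splines: a linear
term plus radial cubic basis functions |x - kappa_k|^3 with the basis
coefficients shrunk towards zero through a hierarchical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import CovariatePanel

__all__ = [
    "SplineSpec",
    "HealthModelState",
    "spline_knots",
    "spline_basis",
    "spline_eval",
    "health_linpred",
    "outcome_loglik",
    "percent_increase",
]

DEFAULT_KNOTS = {"time": 6, "temperature": 3, "rel_humidity": 3}


@dataclass
class SplineSpec:
    """One confounder smoother: s(x) = alpha*x + sum_k b_k |x - kappa_k|^3."""

    name: str
    knots: np.ndarray
    alpha: float = 0.0
    b: np.ndarray | None = None
    smooth_precision: float = 1.0

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, float)
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.b is None:
            self.b = np.zeros(len(self.knots))
        self.b = np.asarray(self.b, float)
        if len(self.b) != len(self.knots):
            raise ValueError("b and knots lengths differ")
        if self.smooth_precision <= 0:
            raise ValueError("smooth_precision must be positive")

    @property
    def n_knots(self) -> int:
        return len(self.knots)


@dataclass
class HealthModelState:
    """Parameters of the health component."""

    beta0: float
    beta: np.ndarray                  # P, per original pollutant unit
    splines: list[SplineSpec] = field(default_factory=list)
    delta: float = 0.0                # holiday effect
    eps: np.ndarray | None = None     # T overdispersion random effects
    sigma_eps: float = 1.0
    health_lag: int = 1

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")
        if self.health_lag < 0:
            raise ValueError("health_lag must be nonnegative")


def spline_knots(x: np.ndarray, K: int) -> np.ndarray:
    """K knots at the j/(K+1) empirical quantiles of x, j = 1..K.

    Quantile placement is the usual mixed-model-spline default; exact ties
    are separated by a deterministic machine-scale perturbation so the knot
    sequence is strictly increasing.
    """
    x = np.asarray(x, float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(np.unique(x)) <= K:
        raise ValueError("too few distinct values to place knots")
    qs = np.arange(1, K + 1) / (K + 1)
    knots = np.quantile(x, qs)
    if np.any(np.diff(knots) <= 0):
        span = max(np.ptp(x), 1.0)
        knots = knots + np.arange(K) * span * 1e-9
    return knots


def spline_basis(x: np.ndarray, knots: np.ndarray, center: bool = True) -> np.ndarray:
    """T x (1+K) design: linear column then |x - kappa_k|^3 columns.

    Columns are sample-centered by default so the smoother is separated from
    the model intercept (an intercept-confounded basis only slows mixing).
    """
    x = np.asarray(x, float)
    B = np.column_stack([x] + [np.abs(x - k) ** 3 for k in knots])
    if center:
        B = B - B.mean(axis=0, keepdims=True)
    return B


def spline_eval(spec: SplineSpec, x: np.ndarray) -> np.ndarray:
    """s(x_t) = alpha*x_t + sum_k b_k |x_t - kappa_k|^3, elementwise (uncentered)."""
    x = np.asarray(x, float)
    out = spec.alpha * x
    for k, bk in zip(spec.knots, spec.b):
        out = out + bk * np.abs(x - k) ** 3
    return out


def health_linpred(state: HealthModelState, mu_orig: np.ndarray,
                   covariates: CovariatePanel | None) -> np.ndarray:
    """log lambda_t for t = health_lag..T-1 (0-based); earlier days excluded.

    Exposure enters at lag ``health_lag`` (previous-day concentration by
    default).  Confounder smoothers and the holiday term are skipped when no
    covariate panel is supplied, reducing to the bare
    log lambda = beta0 + sum_p beta_p mu_{p,t-lag} form.
    """
    mu_orig = np.atleast_2d(np.asarray(mu_orig, float))
    T, P = mu_orig.shape
    if len(state.beta) != P:
        raise ValueError("beta length does not match number of pollutants")
    L = state.health_lag
    if T <= L:
        raise ValueError("need more days than the exposure lag")
    lagged = mu_orig[: T - L] if L > 0 else mu_orig
    eta = state.beta0 + lagged @ state.beta
    if covariates is not None:
        series = {"time": covariates.time_index,
                  "temperature": covariates.temperature,
                  "rel_humidity": covariates.rel_humidity}
        for spec in state.splines:
            eta = eta + spline_eval(spec, series[spec.name])[L:]
        eta = eta + state.delta * covariates.holiday_indicator[L:].astype(float)
    if state.eps is not None:
        eta = eta + np.asarray(state.eps, float)[L:]
    return eta


def outcome_loglik(counts: np.ndarray, linpred: np.ndarray, E: float,
                   start: int = 0) -> float:
    """Sum over t > start of log Poisson(O_t | E * exp(linpred_t)).

    ``counts`` and ``linpred`` are aligned arrays; ``start`` drops leading
    days (those without a lagged exposure) from the likelihood.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    counts = counts[start:].astype(float)
    eta = np.asarray(linpred, float)[start:]
    log_rate = np.log(E) + eta
    return float(np.sum(counts * log_rate - E * np.exp(eta) - gammaln(counts + 1.0)))


def percent_increase(beta_p: float, iqr: float):
    """Percent increase in the event rate for an IQR change in concentration.

    (exp(beta_p * iqr) - 1) * 100; vectorizes over posterior draws of beta_p.
    """
    if np.any(np.asarray(iqr) <= 0):
        raise ValueError("iqr must be positive")
    return (np.exp(np.asarray(beta_p, float) * iqr) - 1.0) * 100.0
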