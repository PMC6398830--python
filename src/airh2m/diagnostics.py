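"""Convergence diagnostics and model comparison.

Convergence is judged the way applied Bayesian time-series analyses usually
do: the Gelman-Rubin potential-scale-reduction statistic across chains, and
a Monte-Carlo-error rule requiring the MC standard error (batch means) to be
below 5% of the posterior standard deviation.  Model comparison uses the
deviance information criterion with the plug-in-mean form of p_D.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "mc_error", "mc_error_ok", "dic"]


def gelman_rubin(draws: np.ndarray) -> float:
    """Potential scale reduction factor for an (n_chains, n) array of draws.

    Standard between/within form: R_hat = sqrt(((n-1)/n * W + B/n) / W).
    """
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    m, n = draws.shape
    chain_means = draws.mean(axis=1)
    B = n * np.var(chain_means, ddof=1)
    W = np.mean(np.var(draws, axis=1, ddof=1))
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def mc_error(draws: np.ndarray) -> float:
    """Batch-means Monte-Carlo standard error with ceil(sqrt(n)) batches."""
    draws = np.asarray(draws, float).ravel()
    n = len(draws)
    if n < 4:
        raise ValueError("too few draws for a batch-means estimate")
    n_batch = int(np.ceil(np.sqrt(n)))
    batch_size = n // n_batch
    trimmed = draws[: n_batch * batch_size].reshape(n_batch, batch_size)
    means = trimmed.mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_batch))


def mc_error_ok(draws: np.ndarray, threshold: float = 0.05) -> bool:
    """True iff the MC standard error is below threshold * posterior sd."""
    draws = np.asarray(draws, float).ravel()
    if len(draws) < 50:
        raise ValueError("need at least 50 draws")
    sd = np.std(draws, ddof=1)
    if sd == 0:
        return False
    return mc_error(draws) < threshold * sd


def dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """(DIC, p_D) from per-draw deviances and the posterior-mean plug-in deviance.

    DIC = D_bar + p_D with p_D = D_bar - D(theta_bar); the plug-in evaluates
    the outcome deviance at the posterior mean of the linear predictor.
    """
    deviance_draws = np.asarray(deviance_draws, float).ravel()
    if not np.all(np.isfinite(deviance_draws)) or not np.isfinite(deviance_at_mean):
        raise ValueError("non-finite deviance")
    d_bar = float(np.mean(deviance_draws))
    p_d = d_bar - float(deviance_at_mean)
    return d_bar + p_d, p_d
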