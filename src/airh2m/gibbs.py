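"""Gibbs-within-Metropolis machinery for the two-component model.

The joint posterior factorises into blocks that are each either conjugate or
well approximated by a local Gaussian, which drives the update scheme:

* latent residual rows theta_t: the Gaussian part (random-walk neighbours +
  measurement layer) is exact; the single Poisson day each row feeds is
  handled by a second-order Taylor term in the proposal and a Metropolis
  correction.  Rows at the same parity of (t // lag) are conditionally
  independent, so the sweep is two batched half-updates (checkerboard).
* covariate coefficients gamma: updated conditional on mu (not theta), which
  makes the step an exact multivariate-Normal draw and leaves the health
  component untouched.
* innovation covariance Sigma_P: conjugate inverse Wishart.
* measurement variances, overdispersion variance: conjugate inverse-Gamma
  forms under either the Uniform-on-sd or the inverse-Gamma prior.
* Poisson coefficient block (intercept, pollutant effects, holiday shift,
  spline coefficients): iterated-weighted-least-squares Metropolis proposal.
* overdispersion effects eps_t: conditionally independent scalar
  Metropolis-Hastings updates with Taylor proposals, fully vectorised.

Nothing here knows about estimator choice; the three fitting strategies are
assembled from these kernels in :mod:`airh2m.estimators`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import invwishart

__all__ = ["ModelData", "GLMLayout", "run_joint_chain", "run_glm_chain"]

ETA_CLIP = 30.0


@dataclass
class ModelData:
    """Everything the sampler needs, on the standardized pollutant scale."""

    Y: np.ndarray                     # T x P standardized measured, NaN where missing
    mask: np.ndarray                  # T x P bool
    center: np.ndarray                # P, standardization centers (0 if none)
    scale: np.ndarray                 # P, standardization scales (1 if none)
    counts: np.ndarray | None = None  # T ints, None for prior-only / pollutant-only
    E: float = 1.0
    health_lag: int = 0
    Xc: np.ndarray | None = None      # T x k covariate design for the pollutant mean
    holiday: np.ndarray | None = None  # T float 0/1
    spline_bases: dict[str, np.ndarray] = field(default_factory=dict)  # name -> T x (1+K)
    overdispersion: bool = False
    lag: int = 1                      # pollutant AR lag

    @property
    def T(self) -> int:
        return self.Y.shape[0]

    @property
    def P(self) -> int:
        return self.Y.shape[1]


@dataclass
class GLMLayout:
    """Column layout of the Poisson design matrix."""

    P: int
    has_holiday: bool
    splines: list[tuple[str, int]]    # (name, K) per smoother

    @property
    def d(self) -> int:
        return 1 + self.P + int(self.has_holiday) + sum(1 + K for _, K in self.splines)

    @property
    def exposure_slice(self) -> slice:
        return slice(1, 1 + self.P)

    @property
    def holiday_index(self) -> int | None:
        return 1 + self.P if self.has_holiday else None

    def spline_slices(self) -> dict[str, tuple[int, slice]]:
        """name -> (alpha column, slice of the K basis columns)."""
        out = {}
        i = 1 + self.P + int(self.has_holiday)
        for name, K in self.splines:
            out[name] = (i, slice(i + 1, i + 1 + K))
            i += 1 + K
        return out

    def prior_precision(self, priors, taus: dict[str, float]) -> np.ndarray:
        prec = np.empty(self.d)
        prec[0] = 1.0 / priors.coef_sd**2
        prec[self.exposure_slice] = 1.0 / priors.beta_sd**2
        if self.has_holiday:
            prec[self.holiday_index] = 1.0 / priors.coef_sd**2
        for name, (ia, sl) in self.spline_slices().items():
            prec[ia] = 1.0 / priors.coef_sd**2
            prec[sl] = taus[name]
        return prec


def make_layout(md: ModelData) -> GLMLayout:
    return GLMLayout(
        P=md.P,
        has_holiday=md.holiday is not None,
        splines=[(n, B.shape[1] - 1) for n, B in md.spline_bases.items()],
    )


def build_fixed_design(md: ModelData, layout: GLMLayout, rows_u: np.ndarray) -> np.ndarray:
    """Design matrix rows for outcome days ``rows_u``; exposure columns left 0."""
    W = np.zeros((len(rows_u), layout.d))
    W[:, 0] = 1.0
    if layout.has_holiday:
        W[:, layout.holiday_index] = md.holiday[rows_u]
    for name, (ia, sl) in layout.spline_slices().items():
        B = md.spline_bases[name]
        W[:, ia] = B[rows_u, 0]
        W[:, sl] = B[rows_u, 1:]
    return W


# ---------------------------------------------------------------------------
# conjugate scalar/covariance updates


def sample_variance(ss: float, n: int, priors, rng) -> float:
    """Draw sigma^2 given a residual sum of squares over n terms."""
    if priors.variance_prior == "invgamma":
        a = priors.invgamma_a + 0.5 * n
        b = priors.invgamma_b + 0.5 * ss
        return b / rng.gamma(a)
    # Uniform(0, sd_upper) on sigma => p(sigma^2) ~ (sigma^2)^(-1/2)
    if n < 2:
        return rng.uniform(0.0, priors.sd_upper) ** 2
    a = 0.5 * (n - 1)
    b = 0.5 * ss
    upper = priors.sd_upper**2
    for _ in range(100):
        v = b / rng.gamma(a)
        if v < upper:
            return v
    return upper * (1 - 1e-12)


def sample_sigma_mat(theta: np.ndarray, lag: int, priors, rng) -> np.ndarray:
    diffs = theta[lag:] - theta[:-lag]
    S = diffs.T @ diffs
    draw = invwishart.rvs(df=priors.iw_df + diffs.shape[0],
                          scale=priors.iw_scale + S, random_state=rng)
    return np.atleast_2d(draw)


def sample_gamma(mu: np.ndarray, Xc: np.ndarray, Siginv: np.ndarray,
                 lag: int, priors, rng) -> np.ndarray:
    """Exact draw of the covariate coefficients conditional on mu.

    With mu held fixed, theta = mu - Xc gamma' enters only the random-walk
    increments and the initialization rows, both Gaussian in gamma.
    """
    T, P = mu.shape
    k = Xc.shape[1]
    dX = Xc[lag:] - Xc[:-lag]
    dmu = mu[lag:] - mu[:-lag]
    Sxx = dX.T @ dX
    prec = np.kron(Siginv, Sxx)
    bvec = (Siginv @ (dmu.T @ dX)).ravel()
    X0 = Xc[:lag]
    s0 = priors.theta_init_sd**2
    prec += np.kron(np.eye(P), (X0.T @ X0)) / s0
    bvec += (mu[:lag].T @ X0).ravel() / s0
    prec += np.eye(P * k) / priors.coef_sd**2
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, bvec)
    z = rng.standard_normal(P * k)
    draw = mean + np.linalg.solve(L.T, z)
    return draw.reshape(P, k)


# ---------------------------------------------------------------------------
# latent theta update (checkerboard)


def _theta_colors(T: int, lag: int) -> list[np.ndarray]:
    blocks = (np.arange(T) // lag) % 2
    return [np.where(blocks == 0)[0], np.where(blocks == 1)[0]]


def update_theta(theta, md: ModelData, m, Siginv, sigma2, b_exp, eta_other,
                 priors, rng, use_outcome: bool):
    """One checkerboard sweep over the latent residual rows (in place).

    ``m`` is the covariate mean (T x P), ``b_exp`` = beta * scale is the
    health-coefficient vector on the standardized scale, ``eta_other`` is a
    length-T array holding, for each outcome day u, the linear predictor
    minus the exposure contribution of theta row u - health_lag (only
    entries for valid outcome days are used).  Returns the acceptance rate.
    """
    T, P = theta.shape
    lag, L = md.lag, md.health_lag
    Y0 = np.nan_to_num(md.Y)
    n_acc = 0
    n_tot = 0
    for idx in _theta_colors(T, lag):
        n = len(idx)
        has_prev = idx >= lag
        has_next = idx + lag < T
        # Gaussian part: AR neighbours + init prior + measurement
        nb_count = has_prev.astype(float) + has_next
        A = nb_count[:, None, None] * Siginv[None, :, :]
        init_rows = idx < lag
        diag_add = np.where(init_rows[:, None], 1.0 / priors.theta_init_sd**2, 0.0)
        Dm = md.mask[idx] / sigma2[None, :]
        diag_idx = np.arange(P)
        A[:, diag_idx, diag_idx] += diag_add + Dm
        rG = np.zeros((n, P))
        prev = np.where(has_prev, idx - lag, 0)
        nxt = np.where(has_next, idx + lag, 0)
        rG += (theta[prev] * has_prev[:, None]) @ Siginv
        rG += (theta[nxt] * has_next[:, None]) @ Siginv
        rG += Dm * (Y0[idx] - m[idx])

        if use_outcome:
            u = idx + L
            active = u < T
            O_u = np.where(active, md.counts[np.minimum(u, T - 1)], 0.0)
            cst = np.where(active, eta_other[np.minimum(u, T - 1)], 0.0)
        else:
            active = np.zeros(n, bool)
            O_u = cst = np.zeros(n)

        cur = theta[idx]

        def taylor(th):
            eta = np.clip(cst + th @ b_exp, -ETA_CLIP, ETA_CLIP)
            w = np.where(active, md.E * np.exp(eta), 0.0)
            g = np.where(active, O_u - w, 0.0)
            return eta, w, g

        def poisson_ll(th):
            eta = np.clip(cst + th @ b_exp, -ETA_CLIP, ETA_CLIP)
            return np.where(active, O_u * eta - md.E * np.exp(eta), 0.0)

        def proposal_params(w, g, th_ref):
            Q = A + w[:, None, None] * np.outer(b_exp, b_exp)[None, :, :]
            r = rG + (g + w * (th_ref @ b_exp))[:, None] * b_exp[None, :]
            Lq = np.linalg.cholesky(Q)
            mean = np.linalg.solve(Q, r[:, :, None])[:, :, 0]
            return Q, Lq, mean

        _, w0, g0 = taylor(cur)
        Q0, L0, mean0 = proposal_params(w0, g0, cur)
        z = rng.standard_normal((n, P, 1))
        prop = mean0 + np.linalg.solve(np.transpose(L0, (0, 2, 1)), z)[:, :, 0]

        if not use_outcome or not active.any():
            theta[idx] = prop
            n_acc += n
            n_tot += n
            continue

        _, w1, g1 = taylor(prop)
        Q1, L1, mean1 = proposal_params(w1, g1, prop)

        def quad(Q, x):
            return np.einsum("ni,nij,nj->n", x, Q, x)

        def logdet(Lc):
            return 2.0 * np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2)), axis=1)

        def gauss_part(th):
            return -0.5 * quad(A, th) + np.sum(rG * th, axis=1)

        log_t = (gauss_part(prop) + poisson_ll(prop)
                 - gauss_part(cur) - poisson_ll(cur))
        log_q_fwd = 0.5 * logdet(L0) - 0.5 * quad(Q0, prop - mean0)
        log_q_rev = 0.5 * logdet(L1) - 0.5 * quad(Q1, cur - mean1)
        log_alpha = log_t + log_q_rev - log_q_fwd
        accept = np.log(rng.uniform(size=n)) < log_alpha
        theta[idx[accept]] = prop[accept]
        n_acc += int(accept.sum())
        n_tot += n
    return n_acc / max(n_tot, 1)


# ---------------------------------------------------------------------------
# Poisson GLM block + overdispersion


def glm_map(c, W, O, off, prior_prec, n_iter: int = 50):
    """Damped-Newton MAP of the Poisson coefficient block (chain initialisation).

    The IWLS-Metropolis proposal is only reliable near the conditional mode;
    a cold start far from it would overshoot and stall the chain.
    """
    def log_target(cv):
        eta = np.clip(W @ cv + off, -ETA_CLIP, ETA_CLIP)
        return float(np.sum(O * (W @ cv) - np.exp(eta)) - 0.5 * np.sum(prior_prec * cv**2))

    cur = log_target(c)
    for _ in range(n_iter):
        eta = np.clip(W @ c + off, -ETA_CLIP, ETA_CLIP)
        w = np.exp(eta)
        g = W.T @ (O - w) - prior_prec * c
        H = (W * w[:, None]).T @ W + np.diag(prior_prec)
        step = np.linalg.solve(H, g)
        lam, cand, new = 1.0, c, cur
        for _ in range(30):
            cand = c + lam * step
            new = log_target(cand)
            if new >= cur:
                break
            lam *= 0.5
        if new < cur:
            break
        gain = new - cur
        c, cur = cand, new
        if gain < 1e-10:
            break
    return c


def update_glm(c, W, O, off, prior_prec, rng):
    """IWLS-Metropolis update of the Poisson coefficient block (returns c, accepted)."""

    def fit_parts(cv):
        eta_lin = W @ cv
        eta = np.clip(eta_lin + off, -ETA_CLIP, ETA_CLIP)
        w = np.exp(eta)
        WtWz = W.T @ (w * eta_lin + (O - w))
        H = (W * w[:, None]).T @ W + np.diag(prior_prec)
        Lh = np.linalg.cholesky(H)
        mean = np.linalg.solve(H, WtWz)
        return eta_lin, H, Lh, mean

    def log_target(cv, eta_lin):
        eta = np.clip(eta_lin + off, -ETA_CLIP, ETA_CLIP)
        return float(np.sum(O * eta_lin - np.exp(eta)) - 0.5 * np.sum(prior_prec * cv**2))

    eta0, H0, L0, m0 = fit_parts(c)
    z = rng.standard_normal(len(c))
    prop = m0 + np.linalg.solve(L0.T, z)
    eta1, H1, L1, m1 = fit_parts(prop)

    def logq(x, H, Lh, mean):
        d = x - mean
        return float(np.sum(np.log(np.diag(Lh))) - 0.5 * d @ H @ d)

    log_alpha = (log_target(prop, eta1) - log_target(c, eta0)
                 + logq(c, H1, L1, m1) - logq(prop, H0, L0, m0))
    if np.log(rng.uniform()) < log_alpha:
        return prop, True
    return c, False


def update_eps(eps, O, eta_c, E, sigma2_eps, rng):
    """Vectorised scalar MH update of the overdispersion effects (in place)."""
    R = E * np.exp(np.clip(eta_c, -ETA_CLIP, ETA_CLIP))

    def parts(e):
        w = R * np.exp(np.clip(e, -ETA_CLIP, ETA_CLIP))
        prec = w + 1.0 / sigma2_eps
        grad = O - w - e / sigma2_eps
        return w, prec, e + grad / prec

    def log_target(e):
        return O * e - R * np.exp(np.clip(e, -ETA_CLIP, ETA_CLIP)) - 0.5 * e**2 / sigma2_eps

    _, prec0, mean0 = parts(eps)
    prop = mean0 + rng.standard_normal(len(eps)) / np.sqrt(prec0)
    _, prec1, mean1 = parts(prop)
    log_alpha = (log_target(prop) - log_target(eps)
                 + 0.5 * np.log(prec1) - 0.5 * prec1 * (eps - mean1) ** 2
                 - 0.5 * np.log(prec0) + 0.5 * prec0 * (prop - mean0) ** 2)
    accept = np.log(rng.uniform(size=len(eps))) < log_alpha
    eps[accept] = prop[accept]
    return float(accept.mean())


# ---------------------------------------------------------------------------
# full chains


def _init_theta(md: ModelData, rng) -> tuple[np.ndarray, np.ndarray | None]:
    """Start theta from the (gap-filled) measurements minus an OLS covariate fit."""
    Yf = md.Y.copy()
    for p in range(md.P):
        col = Yf[:, p]
        obs = np.where(md.mask[:, p])[0]
        if len(obs) == 0:
            col[:] = 0.0
            continue
        col[: obs[0]] = col[obs[0]]
        col[obs[-1] + 1:] = col[obs[-1]]
        bad = ~np.isfinite(col)
        if bad.any():
            col[bad] = np.interp(np.where(bad)[0], obs, col[obs])
    gamma = None
    if md.Xc is not None:
        gamma = np.zeros((md.P, md.Xc.shape[1]))
        for p in range(md.P):
            rows = md.mask[:, p]
            if rows.sum() > md.Xc.shape[1]:
                gamma[p], *_ = np.linalg.lstsq(md.Xc[rows], md.Y[rows, p], rcond=None)
        theta = Yf - md.Xc @ gamma.T
    else:
        theta = Yf
    theta = theta + 0.01 * rng.standard_normal(theta.shape)
    return theta, gamma


def run_joint_chain(md: ModelData, priors, n_burn: int, n_keep: int, rng,
                    use_outcome: bool = True, thin: int = 1,
                    record_mu: bool = False, prior_only: bool = False):
    """One chain of the joint (or pollutant-only) sampler.

    ``use_outcome=False`` cuts the health component entirely (stage 1 of the
    two-stage estimator, and the pollutant half of prior-only audits).
    ``prior_only`` additionally empties the measurement mask so every block
    samples from its prior.
    """
    md_T, P = md.T, md.P
    is_prior_only = prior_only
    if prior_only:
        md = ModelData(**{**vars(md), "mask": np.zeros_like(md.mask),
                          "counts": None})
        use_outcome = False
    if md.counts is None:
        use_outcome = False
    L = md.health_lag
    layout = make_layout(md)
    rows_u = np.arange(L, md_T)
    Wfix = build_fixed_design(md, layout, rows_u)
    O_eff = md.counts[rows_u].astype(float) if use_outcome else None

    theta, gamma = _init_theta(md, rng)
    if prior_only:
        theta = priors.theta_init_sd * 0.01 * rng.standard_normal((md_T, P))
        if gamma is not None:
            gamma[:] = 0.0
    m = md.Xc @ gamma.T if gamma is not None else np.zeros((md_T, P))
    d0 = np.diff(theta, axis=0)
    Sigma = d0.T @ d0 / max(len(d0), 1) + 1e-3 * np.eye(P)
    if prior_only:
        Sigma = priors.iw_scale / max(priors.iw_df, P + 2)
    sigma2 = np.full(P, 0.25)
    c = np.zeros(layout.d)
    taus = {name: priors.spline_gamma_a / priors.spline_gamma_b
            for name, _ in layout.splines}
    eps = np.zeros(md_T - L) if md.overdispersion else None
    sigma2_eps = 0.01
    if use_outcome:
        c[0] = np.log(max(np.mean(O_eff), 0.5) / md.E)
        mu0 = m + theta
        W0 = Wfix.copy()
        mu0_orig = md.center[None, :] + md.scale[None, :] * mu0
        W0[:, layout.exposure_slice] = mu0_orig[rows_u - L] if L > 0 else mu0_orig
        c = glm_map(c, W0, O_eff, np.log(md.E),
                    layout.prior_precision(priors, taus))

    n_iter = n_burn + n_keep * thin
    draws: dict[str, list] = {k: [] for k in
                              ["beta0", "beta", "sigma_proc", "Sigma_P", "deviance"]}
    if gamma is not None:
        draws["gamma"] = []
    if layout.has_holiday:
        draws["delta"] = []
    for name, _ in layout.splines:
        draws[f"alpha_{name}"] = []
        draws[f"b_{name}"] = []
        draws[f"tau_{name}"] = []
    if md.overdispersion:
        draws["sigma_eps"] = []
    mu_draws = [] if record_mu else None
    mu_sum = np.zeros((md_T, P))
    eta_sum = np.zeros(md_T - L)
    imp_sum = np.zeros((md_T, P))
    n_rec = 0
    acc_theta = []

    any_missing = bool((~md.mask).any()) and not prior_only

    for it in range(n_iter):
        Siginv = np.linalg.inv(Sigma)
        mu = m + theta
        mu_orig = md.center[None, :] + md.scale[None, :] * mu
        beta = c[layout.exposure_slice]
        b_exp = beta * md.scale

        if use_outcome:
            W = Wfix.copy()
            W[:, layout.exposure_slice] = mu_orig[rows_u - L] if L > 0 else mu_orig
            eta_lin = W @ c
            eta_full = eta_lin + (eps if eps is not None else 0.0)
            # eta_other[u]: linear predictor minus this row's theta exposure term
            eta_other = np.zeros(md_T)
            eta_other[rows_u] = eta_full - (theta[rows_u - L] if L > 0 else theta) @ b_exp
        else:
            eta_other = np.zeros(md_T)

        acc = update_theta(theta, md, m, Siginv, sigma2, b_exp, eta_other,
                           priors, rng, use_outcome)
        acc_theta.append(acc)
        mu = m + theta
        if gamma is not None:
            gamma = sample_gamma(mu, md.Xc, Siginv, md.lag, priors, rng)
            m = md.Xc @ gamma.T
            theta = mu - m
        Sigma = sample_sigma_mat(theta, md.lag, priors, rng)
        resid = np.where(md.mask, np.nan_to_num(md.Y) - mu, 0.0)
        for p in range(P):
            n_p = int(md.mask[:, p].sum())
            sigma2[p] = sample_variance(float(np.sum(resid[:, p] ** 2)), n_p,
                                        priors, rng)

        if use_outcome:
            mu_orig = md.center[None, :] + md.scale[None, :] * mu
            W = Wfix.copy()
            W[:, layout.exposure_slice] = mu_orig[rows_u - L] if L > 0 else mu_orig
            off = np.log(md.E) + (eps if eps is not None else 0.0)
            prior_prec = layout.prior_precision(priors, taus)
            c, _ = update_glm(c, W, O_eff, off, prior_prec, rng)
            eta_lin = W @ c
            if md.overdispersion:
                update_eps(eps, O_eff, np.log(md.E) + eta_lin, 1.0, sigma2_eps, rng)
                sigma2_eps = sample_variance(float(np.sum(eps**2)), len(eps),
                                             priors, rng)
            for name, (ia, sl) in layout.spline_slices().items():
                bcoef = c[sl]
                taus[name] = rng.gamma(priors.spline_gamma_a + 0.5 * len(bcoef),
                                       1.0 / (priors.spline_gamma_b
                                              + 0.5 * float(np.sum(bcoef**2))))
        elif is_prior_only:
            # no likelihood anywhere: every health-block quantity comes
            # straight from its prior
            for name, _ in layout.splines:
                taus[name] = rng.gamma(priors.spline_gamma_a,
                                       1.0 / priors.spline_gamma_b)
            prior_prec = layout.prior_precision(priors, taus)
            c = rng.standard_normal(layout.d) / np.sqrt(prior_prec)
            if md.overdispersion:
                if priors.variance_prior == "uniform_sd":
                    sigma2_eps = rng.uniform(0, priors.sd_upper) ** 2
                else:
                    sigma2_eps = priors.invgamma_b / rng.gamma(priors.invgamma_a)
                eps = np.sqrt(sigma2_eps) * rng.standard_normal(md_T - L)

        if it >= n_burn and (it - n_burn) % thin == 0:
            draws["beta0"].append(c[0])
            draws["beta"].append(c[layout.exposure_slice].copy())
            draws["sigma_proc"].append(np.sqrt(sigma2))
            draws["Sigma_P"].append(Sigma.copy())
            if gamma is not None:
                draws["gamma"].append(gamma.copy())
            if layout.has_holiday:
                draws["delta"].append(c[layout.holiday_index])
            for name, (ia, sl) in layout.spline_slices().items():
                draws[f"alpha_{name}"].append(c[ia])
                draws[f"b_{name}"].append(c[sl].copy())
                draws[f"tau_{name}"].append(taus[name])
            if md.overdispersion:
                draws["sigma_eps"].append(np.sqrt(sigma2_eps))
            mu = m + theta
            mu_sum += mu
            if mu_draws is not None:
                mu_draws.append(mu.copy())
            if any_missing:
                imp = mu + np.sqrt(sigma2)[None, :] * rng.standard_normal((md_T, P))
                imp_sum += np.where(md.mask, 0.0, imp)
            if use_outcome:
                mu_orig = md.center[None, :] + md.scale[None, :] * mu
                W = Wfix.copy()
                W[:, layout.exposure_slice] = mu_orig[rows_u - L] if L > 0 else mu_orig
                eta = W @ c + (eps if eps is not None else 0.0)
                eta_sum += eta
                draws["deviance"].append(_deviance(O_eff, eta, md.E))
            else:
                draws["deviance"].append(np.nan)
            n_rec += 1

    out = {k: np.asarray(v) for k, v in draws.items()}
    extras = {
        "mu_mean": mu_sum / max(n_rec, 1),
        "eta_mean": eta_sum / max(n_rec, 1) if use_outcome else None,
        "theta_accept": float(np.mean(acc_theta)),
        "imputed_mean": imp_sum / max(n_rec, 1) if any_missing else None,
        "n_missing_cells": int((~md.mask).sum()),
    }
    if mu_draws is not None:
        extras["mu_draws"] = np.asarray(mu_draws)
    return out, extras


def _deviance(O, eta, E):
    from scipy.special import gammaln
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    log_rate = np.log(E) + eta
    return float(-2.0 * np.sum(O * log_rate - E * np.exp(eta) - gammaln(O + 1.0)))


def run_glm_chain(md: ModelData, priors, n_burn: int, n_keep: int, rng,
                  rows_u: np.ndarray, exposure_fn, thin: int = 1):
    """Health-component-only chain (plug-in or cut-exposure estimators).

    ``exposure_fn(iteration)`` returns the (len(rows_u), P) original-unit
    exposure matrix for that iteration: constant for the plug-in model,
    cycling over first-stage posterior draws for the cut model.
    """
    layout = make_layout(md)
    Wfix = build_fixed_design(md, layout, rows_u)
    O_eff = md.counts[rows_u].astype(float)
    taus = {name: priors.spline_gamma_a / priors.spline_gamma_b
            for name, _ in layout.splines}
    c = np.zeros(layout.d)
    c[0] = np.log(max(np.mean(O_eff), 0.5) / md.E)
    W0 = Wfix.copy()
    W0[:, layout.exposure_slice] = exposure_fn(0)
    c = glm_map(c, W0, O_eff, np.log(md.E), layout.prior_precision(priors, taus))
    eps = np.zeros(len(rows_u)) if md.overdispersion else None
    sigma2_eps = 0.01

    n_iter = n_burn + n_keep * thin
    draws: dict[str, list] = {k: [] for k in ["beta0", "beta", "deviance"]}
    if layout.has_holiday:
        draws["delta"] = []
    for name, _ in layout.splines:
        draws[f"alpha_{name}"] = []
        draws[f"b_{name}"] = []
        draws[f"tau_{name}"] = []
    if md.overdispersion:
        draws["sigma_eps"] = []
    eta_sum = np.zeros(len(rows_u))
    n_rec = 0

    for it in range(n_iter):
        W = Wfix.copy()
        W[:, layout.exposure_slice] = exposure_fn(it)
        off = np.log(md.E) + (eps if eps is not None else 0.0)
        prior_prec = layout.prior_precision(priors, taus)
        c, _ = update_glm(c, W, O_eff, off, prior_prec, rng)
        eta_lin = W @ c
        if md.overdispersion:
            update_eps(eps, O_eff, np.log(md.E) + eta_lin, 1.0, sigma2_eps, rng)
            sigma2_eps = sample_variance(float(np.sum(eps**2)), len(eps), priors, rng)
        for name, (ia, sl) in layout.spline_slices().items():
            bcoef = c[sl]
            taus[name] = rng.gamma(priors.spline_gamma_a + 0.5 * len(bcoef),
                                   1.0 / (priors.spline_gamma_b
                                          + 0.5 * float(np.sum(bcoef**2))))
        if it >= n_burn and (it - n_burn) % thin == 0:
            draws["beta0"].append(c[0])
            draws["beta"].append(c[layout.exposure_slice].copy())
            if layout.has_holiday:
                draws["delta"].append(c[layout.holiday_index])
            for name, (ia, sl) in layout.spline_slices().items():
                draws[f"alpha_{name}"].append(c[ia])
                draws[f"b_{name}"].append(c[sl].copy())
                draws[f"tau_{name}"].append(taus[name])
            if md.overdispersion:
                draws["sigma_eps"].append(np.sqrt(sigma2_eps))
            eta = eta_lin + (eps if eps is not None else 0.0)
            eta_sum += eta
            draws["deviance"].append(_deviance(O_eff, eta, md.E))
            n_rec += 1

    out = {k: np.asarray(v) for k, v in draws.items()}
    extras = {"eta_mean": eta_sum / max(n_rec, 1), "rows_u": rows_u}
    return out, extras
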