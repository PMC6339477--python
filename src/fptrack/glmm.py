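"""Binomial random-intercept mixed model for search probability on habitat ranks.

The model: for fix j of bird i, y_ij ~ Bernoulli(p_ij) with

    logit(p_ij) = x_ij' beta + alpha_i,     alpha_i ~ Normal(0, sigma^2)

where x carries an intercept and the three ranked covariates (SST, turbidity,
chlorophyll-a, each on the 0–20 rank scale) and the random intercept absorbs
consistent between-individual differences in search propensity.

Estimation maximises the exact marginal likelihood — the random intercept
integrated out per group — by adaptive Gauss–Hermite quadrature: the
integrand is re-centred at its mode (found by Newton per group) and scaled by
its curvature, so even one node (the Laplace approximation) is accurate and
25 nodes are effectively exact for a one-dimensional integral.  The optimiser
works on (beta, log sigma); standard errors come from the inverse observed
information (finite-difference Hessian of the marginal log-likelihood).

Goodness of fit is summarised by the latent-scale variance-partition R²:
with sigma_f² = var(X beta-hat) the fixed-effect variance and pi²/3 the
logit-link distribution-specific variance,

    R²_marginal    = sigma_f² / (sigma_f² + sigma² + pi²/3)
    R²_conditional = (sigma_f² + sigma²) / (sigma_f² + sigma² + pi²/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

LOGIT_RESIDUAL_VAR = np.pi ** 2 / 3.0


@dataclass
class ModelData:
    """Response, design matrix and grouping for the mixed model.

    ``y`` is 1 for search, 0 for travel.  Rows with any missing covariate
    are dropped at construction (count logged).
    """

    y: np.ndarray
    X: np.ndarray
    group: np.ndarray
    colnames: list[str] = field(default_factory=lambda: ["intercept"])

    @classmethod
    def from_frame(cls, df, covariates=("sst_rank", "turbidity_rank", "chla_rank"),
                   response: str = "y", group: str = "individual_id") -> "ModelData":
        cols = [response, group, *covariates]
        sub = df[cols]
        n0 = len(sub)
        sub = sub.dropna()
        if len(sub) < n0:
            logger.info("dropped %d rows with missing covariates", n0 - len(sub))
        X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in covariates])
        return cls(
            y=sub[response].to_numpy(float),
            X=X,
            group=sub[group].to_numpy(),
            colnames=["intercept", *covariates],
        )

    def group_index(self) -> tuple[np.ndarray, int]:
        uniq, idx = np.unique(self.group, return_inverse=True)
        return idx, len(uniq)


@dataclass
class GlmmFit:
    """Fitted mixed model: logit-scale estimates and inference summaries."""

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma2_alpha: float
    loglik: float
    r2_marginal: float | None
    r2_conditional: float | None
    converged: bool
    colnames: list[str]
    boundary_sigma: bool = False
    n_obs: int = 0
    n_groups: int = 0

    def summary_table(self) -> str:
        """Coefficient table with Wald tests and the two R² values."""
        lines = [f"{'Parameter':<18}{'Estimate':>10}{'SE':>9}{'Z':>8}{'P-value':>10}"]
        for k, name in enumerate(self.colnames):
            pv = f"{self.p[k]:.3f}" if self.p[k] >= 0.001 else "<0.001"
            lines.append(f"{name:<18}{self.beta[k]:>10.3f}{self.se[k]:>9.3f}"
                         f"{self.z[k]:>8.2f}{pv:>10}")
        lines.append(f"random intercept variance: {self.sigma2_alpha:.3f}")
        if self.r2_marginal is not None:
            lines.append(f"R2 cond./marg.: {self.r2_conditional:.2f}/{self.r2_marginal:.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                n: {"estimate": float(b), "se": float(s), "z": float(z), "p": float(p)}
                for n, b, s, z, p in zip(self.colnames, self.beta, self.se, self.z, self.p)
            },
            "sigma2_alpha": float(self.sigma2_alpha),
            "loglik": float(self.loglik),
            "r2_marginal": None if self.r2_marginal is None else float(self.r2_marginal),
            "r2_conditional": None if self.r2_conditional is None else float(self.r2_conditional),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
        }


def _bernoulli_loglik_terms(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # log p for y=1, log(1-p) for y=0, numerically stable
    return log_expit((2.0 * y - 1.0) * eta)


def _group_modes(eta0, y, gidx, ngroups, sigma2, tol=1e-10, max_iter=50, a0=None):
    """Per-group posterior modes of the random intercept (damped Newton)."""
    a = np.zeros(ngroups) if a0 is None else a0.copy()
    h = None
    for _ in range(max_iter):
        eta = eta0 + a[gidx]
        p = expit(eta)
        g = np.bincount(gidx, weights=y - p, minlength=ngroups) - a / sigma2
        h = np.bincount(gidx, weights=p * (1 - p), minlength=ngroups) + 1.0 / sigma2
        step = g / h
        step = np.clip(step, -4.0, 4.0)
        a = a + step
        if np.max(np.abs(g)) < tol:
            break
    eta = eta0 + a[gidx]
    p = expit(eta)
    h = np.bincount(gidx, weights=p * (1 - p), minlength=ngroups) + 1.0 / sigma2
    return a, h


def marginal_loglik(beta, log_sigma, y, X, gidx, ngroups, nodes: int = 25,
                    _mode_cache: dict | None = None) -> float:
    """Marginal log-likelihood with the random intercept integrated out.

    ``_mode_cache`` optionally carries the previous per-group modes between
    calls (warm start for the inner Newton solve during optimisation).
    """
    sigma = np.exp(log_sigma)
    sigma2 = sigma ** 2
    eta0 = X @ beta
    a0 = None if _mode_cache is None else _mode_cache.get("a")
    a_hat, h = _group_modes(eta0, y, gidx, ngroups, sigma2, a0=a0)
    if _mode_cache is not None:
        _mode_cache["a"] = a_hat
    xk, wk = _hermgauss_cached(nodes)
    scale = np.sqrt(2.0 / h)                      # (ngroups,)
    A = a_hat[:, None] + scale[:, None] * xk[None, :]   # (ngroups, nodes)
    # per-(group,node) joint log density, group-summed in one bincount
    K = len(xk)
    terms = _bernoulli_loglik_terms(y[:, None], eta0[:, None] + A[gidx, :])
    flat = (gidx[:, None] * K + np.arange(K)[None, :]).ravel()
    ll = np.bincount(flat, weights=terms.ravel(), minlength=ngroups * K).reshape(ngroups, K)
    logjoint = ll + norm.logpdf(A, scale=sigma)
    logint = np.log(scale) + _logsumexp(np.log(wk)[None, :] + xk[None, :] ** 2 + logjoint, axis=1)
    return float(np.sum(logint))


_HERMGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _hermgauss_cached(nodes: int):
    if nodes not in _HERMGAUSS_CACHE:
        _HERMGAUSS_CACHE[nodes] = hermgauss(nodes)
    return _HERMGAUSS_CACHE[nodes]


def _logsumexp(x, axis):
    m = np.max(x, axis=axis, keepdims=True)
    return np.squeeze(m, axis=axis) + np.log(np.sum(np.exp(x - m), axis=axis))


def _logistic_irls(y, X, tol=1e-12, max_iter=100):
    """Plain logistic regression by Newton iteration (no random effect)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        g = X.T @ (y - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(g)) < tol:
            break
    return beta


def _fd_hessian(f, theta, rel_step=1e-4):
    """Central finite-difference Hessian of scalar f at theta."""
    k = len(theta)
    h = rel_step * (1.0 + np.abs(theta))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * h[i] * h[j])
    return H


def _fd_gradient(f, theta, rel_step=1e-6):
    g = np.empty(len(theta))
    for i in range(len(theta)):
        h = rel_step * (1.0 + abs(theta[i]))
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2 * h)
    return g


def _newton_polish(f, theta, H, max_steps=5):
    """Damped Newton refinement of a minimiser; returns (theta, H, |grad|)."""
    fval = f(theta)
    g = _fd_gradient(f, theta)
    for _ in range(max_steps):
        if np.max(np.abs(g)) < 1e-7:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        moved = False
        for damp in (1.0, 0.5, 0.25, 0.1):
            cand = theta - damp * step
            fc = f(cand)
            if fc < fval:
                theta, fval, moved = cand, fc, True
                break
        if not moved:
            break
        H = _fd_hessian(f, theta)
        g = _fd_gradient(f, theta)
    return theta, H, float(np.max(np.abs(g)))


def fit_binomial_glmm(data: ModelData, quadrature_nodes: int = 25,
                      constrain_sigma_zero: bool = False,
                      compute_r2: bool = True) -> GlmmFit:
    """Fit the binomial random-intercept model by adaptive Gauss–Hermite ML.

    ``quadrature_nodes=1`` is the Laplace approximation.  With
    ``constrain_sigma_zero`` the model collapses to plain logistic regression
    (used for the no-random-effect limit and as the optimiser's start).
    Non-convergence returns a fit flagged ``converged=False``; a variance
    estimate at the zero boundary is flagged ``boundary_sigma``.
    """
    y, X = data.y, data.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    gidx, ngroups = data.group_index()
    n, k = X.shape

    beta0 = _logistic_irls(y, X)

    if constrain_sigma_zero:
        eta = X @ beta0
        p = expit(eta)
        H = X.T @ (X * (p * (1 - p))[:, None])
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        ll = float(np.sum(_bernoulli_loglik_terms(y, eta)))
        z = beta0 / se
        fit = GlmmFit(beta0, se, z, 2 * norm.sf(np.abs(z)), 0.0, ll, None, None,
                      True, list(data.colnames), n_obs=n, n_groups=ngroups)
        if compute_r2:
            fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit, data)
        return fit

    if ngroups < 2:
        logger.warning("fewer than 2 groups: random intercept is not meaningful")

    cache: dict = {}

    def nll(theta):
        return -marginal_loglik(theta[:k], theta[k], y, X, gidx, ngroups,
                                nodes=quadrature_nodes, _mode_cache=cache)

    theta0 = np.append(beta0, 0.0)  # log sigma = 0 start
    res = minimize(nll, theta0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    theta = res.x
    H = _fd_hessian(nll, theta)
    # polish with damped Newton steps on the exact objective: BFGS line
    # searches can stop on precision loss slightly short of the optimum
    theta, H, grad_norm = _newton_polish(nll, theta, H)
    converged = bool(res.success) or grad_norm < 1e-3
    beta = theta[:k]
    sigma = float(np.exp(theta[k]))
    boundary = sigma < 1e-3
    if boundary:
        logger.warning("random-intercept SD estimate at the zero boundary (%.2e)", sigma)
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:k]
        if np.all(d > 0):
            se = np.sqrt(d)
        else:
            logger.warning("non-positive information diagonal; SEs missing")
    except np.linalg.LinAlgError:
        logger.warning("singular observed information; SEs missing")

    z = beta / se
    fit = GlmmFit(beta, se, z, 2 * norm.sf(np.abs(z)), sigma ** 2, -res.fun,
                  None, None, converged, list(data.colnames),
                  boundary_sigma=boundary, n_obs=n, n_groups=ngroups)
    if compute_r2:
        fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit, data)
    return fit


def nakagawa_r2(fit: GlmmFit, data: ModelData) -> tuple[float, float]:
    """Marginal and conditional variance-partition R² on the latent scale."""
    sigma_f2 = float(np.var(data.X @ fit.beta))
    denom = sigma_f2 + fit.sigma2_alpha + LOGIT_RESIDUAL_VAR
    return sigma_f2 / denom, (sigma_f2 + fit.sigma2_alpha) / denom


def predict_search_probability(fit: GlmmFit, ranks: dict[str, float] | np.ndarray,
                               reference_rank: float = 10.0) -> float:
    """Population-level search probability (random effect at zero).

    ``ranks`` may be a full covariate vector (without intercept) or a dict
    naming some covariates; unnamed ones are held at ``reference_rank``
    (mid-rank 10), which is how partial-effect curves are drawn.
    """
    names = fit.colnames[1:]
    if isinstance(ranks, dict):
        x = np.array([ranks.get(n.replace("_rank", ""), ranks.get(n, reference_rank))
                      for n in names], dtype=float)
    else:
        x = np.asarray(ranks, dtype=float)
    if np.any((x < 0) | (x > 20)):
        logger.warning("rank value outside [0, 20]; computing anyway")
    return float(expit(fit.beta[0] + x @ fit.beta[1:]))
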