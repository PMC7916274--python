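"""Random-effects panel estimators for the two-part expenditure model.

Two estimators are provided, one per equation of the two-part model:

* :func:`fit_re_logit` — a random-intercept logit for the any-use outcome.
  The individual-specific normal intercept ``alpha_i ~ N(0, sigma_alpha^2)``
  is integrated out of each individual's likelihood contribution by adaptive
  Gauss-Hermite quadrature (nodes centred and scaled at the per-individual
  posterior mode), and the marginal likelihood is maximized by quasi-Newton
  ascent with an analytic score. Standard errors come from the observed
  information at the optimum.

* :func:`fit_re_gls` — the classic random-effects estimator for log
  expenditure among users: Swamy-Arora variance components (within residual
  variance from the fixed-effects regression, between variance from the
  group-means regression) followed by feasible GLS via quasi-demeaning.
  Standard errors are cluster-robust by individual.

Both return an :class:`REFit`, the container every downstream prediction
consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, roots_hermite, logsumexp

from .exceptions import DegenerateOutcomeError, FitFailureError, SchemaError

logger = logging.getLogger(__name__)

_LOG_SIGMA_FLOOR = np.log(1e-4)


@dataclass
class REFit:
    """A fitted random-effects model.

    ``sigma_alpha`` is the random-intercept SD; ``sigma_u`` the residual SD
    (cost model only, None for the logit). ``smearing_factor`` is Duan's
    retransformation factor, the sample mean of exponentiated level-1
    residuals (cost model only).
    """

    model: str  # "re_logit" | "re_gls"
    coefficients: dict
    std_errors: dict
    sigma_alpha: float
    sigma_u: float | None
    log_likelihood: float | None
    n_obs: int
    n_individuals: int
    converged: bool
    iterations: int
    smearing_factor: float | None = None
    design_columns: tuple = ()

    def coef_array(self, columns=None) -> np.ndarray:
        cols = columns if columns is not None else self.design_columns
        return np.array([self.coefficients[c] for c in cols])

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["design_columns"] = list(self.design_columns)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "REFit":
        with open(path) as fh:
            payload = json.load(fh)
        payload["design_columns"] = tuple(payload["design_columns"])
        return cls(**payload)


def _as_groups(groups) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(groups))
    return codes


# ---------------------------------------------------------------------------
# Random-effects logit


def _posterior_modes(eta, y, group_codes, n_groups, sigma, iters=25, init=None):
    """Per-individual mode and curvature of the integrand over alpha.

    The log integrand log prod_t p(y_it | alpha) + log phi(alpha; 0, sigma^2)
    is strictly concave in alpha, so Newton steps converge quickly; ``init``
    warm-starts from the previous modes.
    """
    m = np.zeros(n_groups) if init is None else init.copy()
    sigma2 = max(sigma, 1e-8) ** 2
    for _ in range(iters):
        mu = expit(eta + m[group_codes])
        g = np.bincount(group_codes, weights=y - mu, minlength=n_groups) - m / sigma2
        h = -np.bincount(group_codes, weights=mu * (1 - mu), minlength=n_groups) - 1.0 / sigma2
        step = g / h
        m = m - step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = expit(eta + m[group_codes])
    h = -np.bincount(group_codes, weights=mu * (1 - mu), minlength=n_groups) - 1.0 / sigma2
    return m, np.sqrt(-1.0 / h)


class _FrozenQuadrature:
    """Gauss-Hermite approximation with per-individual nodes held fixed.

    With nodes frozen, the approximate marginal log likelihood and its score
    in (beta, log sigma) are exact analytic expressions; re-freezing at the
    current parameters between inner maximizations yields the self-consistent
    adaptive-quadrature MLE.
    """

    def __init__(self, X, y, group_codes, n_groups, nodes, modes, scales):
        gh_x, gh_w = roots_hermite(nodes)
        # a_ik = m_i + sqrt(2) s_i x_k ; log c_ik = log(sqrt(2) s_i w_k e^{x_k^2})
        self.a = modes[:, None] + np.sqrt(2.0) * scales[:, None] * gh_x[None, :]
        self.logc = (
            np.log(np.sqrt(2.0) * scales)[:, None]
            + (np.log(gh_w) + gh_x**2)[None, :]
        )
        self.X, self.y = X, y
        self.gc, self.n_groups = group_codes, n_groups
        self.nodes = nodes

    def loglik_and_score(self, params):
        X, y, gc = self.X, self.y, self.gc
        k = X.shape[1]
        beta, log_sigma = params[:k], params[k]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        z = eta[:, None] + self.a[gc, :]  # (n_obs, K)
        logp_obs = np.where(y[:, None] > 0.5, log_expit(z), log_expit(-z))
        S = np.zeros((self.n_groups, self.nodes))
        for kk in range(self.nodes):
            S[:, kk] = np.bincount(gc, weights=logp_obs[:, kk], minlength=self.n_groups)
        log_phi = -0.5 * np.log(2 * np.pi) - log_sigma - 0.5 * (self.a / sigma) ** 2
        log_terms = S + log_phi + self.logc
        log_L = logsumexp(log_terms, axis=1)
        ll = float(log_L.sum())

        q = np.exp(log_terms - log_L[:, None])  # posterior node weights, rows sum to 1
        mu = expit(z)
        r = np.einsum("nk,nk->n", q[gc, :], y[:, None] - mu)
        g_beta = X.T @ r
        g_logsigma = float(np.sum(q * ((self.a / sigma) ** 2 - 1.0)))
        return ll, np.concatenate([g_beta, [g_logsigma]])


def re_logit_loglik(beta, sigma_alpha, X, y, groups, nodes=15, adaptive=True):
    """Adaptive Gauss-Hermite marginal log likelihood at given parameters.

    Exposed so the approximation can be validated against dense numerical
    integration on small panels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gc = _as_groups(groups)
    n_groups = gc.max() + 1
    beta = np.asarray(beta, dtype=float)
    sigma = float(sigma_alpha)
    eta = X @ beta
    if adaptive and sigma > 0:
        modes, scales = _posterior_modes(eta, y, gc, n_groups, sigma)
    else:
        modes = np.zeros(n_groups)
        scales = np.full(n_groups, max(sigma, 1e-8))
    quad = _FrozenQuadrature(X, y, gc, n_groups, nodes, modes, scales)
    ll, _ = quad.loglik_and_score(np.concatenate([beta, [np.log(max(sigma, 1e-8))]]))
    return ll


def pooled_logit_loglik(beta, X, y):
    """Log likelihood of the plain (sigma_alpha = 0) logit."""
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    y = np.asarray(y, float)
    return float(np.sum(np.where(y > 0.5, log_expit(eta), log_expit(-eta))))


def fit_re_logit(
    X,
    y,
    groups,
    design_columns=None,
    quadrature_nodes: int = 15,
    tolerance: float = 1e-6,
    max_iterations: int = 200,
    compute_se: bool = True,
) -> REFit:
    """Maximum likelihood for the random-intercept logit.

    ``X`` may be a DataFrame (column names become coefficient keys) or an
    array with ``design_columns`` supplied. ``groups`` identifies individuals.
    Optimization alternates (a) re-centring the quadrature at the current
    per-individual posterior modes with (b) quasi-Newton maximization of the
    frozen-node likelihood, until the marginal log likelihood is stable to
    ``tolerance`` (relative).
    """
    if isinstance(X, pd.DataFrame):
        design_columns = tuple(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        design_columns = tuple(
            design_columns
            if design_columns is not None
            else [f"x{i}" for i in range(Xv.shape[1])]
        )
    yv = np.asarray(y, dtype=float)
    if yv.min() == yv.max():
        raise DegenerateOutcomeError("use outcome is constant; logit unidentified")
    gc = _as_groups(groups)
    n_groups = int(gc.max()) + 1
    n_obs, k = Xv.shape

    # start values: pooled logit (sigma profiled at ~0), then free sigma
    theta = np.zeros(k + 1)
    theta[k] = np.log(0.5)
    pooled = minimize(
        lambda b: -pooled_logit_loglik(b, Xv, yv),
        np.zeros(k),
        jac=lambda b: -(Xv.T @ (yv - expit(Xv @ b))),
        method="L-BFGS-B",
    )
    theta[:k] = pooled.x

    bounds = [(None, None)] * k + [(_LOG_SIGMA_FLOOR, 3.0)]
    state = {"modes": np.zeros(n_groups)}

    def negll(t):
        # re-adapt nodes at the current parameters; the score neglects the
        # node dependence, a second-order term since the modes are stationary
        # points of the integrand
        sigma_t = np.exp(t[k])
        modes, scales = _posterior_modes(
            Xv @ t[:k], yv, gc, n_groups, sigma_t, iters=8, init=state["modes"]
        )
        state["modes"] = modes
        quad = _FrozenQuadrature(
            Xv, yv, gc, n_groups, quadrature_nodes, modes, scales
        )
        ll, g = quad.loglik_and_score(t)
        return -ll, -g

    trace = []
    res = minimize(
        negll,
        theta,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iterations, "ftol": tolerance * 1e-4, "gtol": 1e-7},
    )
    theta = res.x
    total_iters = int(res.nit)
    trace.append(-res.fun)
    # the approximate score can stall the line search harmlessly once the
    # gradient is already tiny; accept that as convergence
    grad_norm = float(np.max(np.abs(res.jac)))
    if not (res.success or grad_norm < 1e-3 * (abs(res.fun) + 1.0)):
        raise FitFailureError(
            f"random-effects logit did not converge: {res.message}", trace
        )

    sigma = float(np.exp(theta[k]))
    # re-adapt once more at the optimum for the reported likelihood & Hessian
    modes, scales = _posterior_modes(Xv @ theta[:k], yv, gc, n_groups, sigma)
    quad = _FrozenQuadrature(Xv, yv, gc, n_groups, quadrature_nodes, modes, scales)
    ll, _ = quad.loglik_and_score(theta)

    se = np.full(k, np.nan)
    if compute_se:
        H = np.zeros((k + 1, k + 1))
        h = 1e-5
        for j in range(k + 1):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            _, gp = quad.loglik_and_score(tp)
            _, gm = quad.loglik_and_score(tm)
            H[j] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        # pinv tolerates an unidentified direction (e.g. an all-zero design
        # cell), whose reported SE is then meaningless but finite
        cov = np.linalg.pinv(-H, hermitian=True)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))

    return REFit(
        model="re_logit",
        coefficients={c: float(b) for c, b in zip(design_columns, theta[:k])},
        std_errors={c: float(s) for c, s in zip(design_columns, se)},
        sigma_alpha=sigma,
        sigma_u=None,
        log_likelihood=float(ll),
        n_obs=n_obs,
        n_individuals=n_groups,
        converged=True,
        iterations=total_iters,
        design_columns=design_columns,
    )


def adjusted_odds_ratios(fit: REFit) -> dict:
    """Exponentiated logit coefficients, excluding the intercept."""
    if fit.model != "re_logit":
        raise SchemaError("adjusted odds ratios are defined for the use equation only")
    if not fit.converged:
        raise FitFailureError("fit did not converge; aOR not reported")
    return {
        c: float(np.exp(b)) for c, b in fit.coefficients.items() if c != "const"
    }


# ---------------------------------------------------------------------------
# Random-effects GLS for log expenditure


def fit_re_gls(
    X,
    expenditure,
    groups,
    design_columns=None,
    cluster_robust: bool = True,
    variance_components: tuple | None = None,
) -> REFit:
    """Swamy-Arora feasible GLS for log expenditure among users.

    The outcome is the strictly positive expenditure; the log is taken here.
    Variance components: the level-1 residual variance from the within
    (fixed-effects) regression, the intercept variance from the group-means
    (between) regression with the Swamy-Arora correction; a negative between
    estimate is clamped to zero (and logged). Coefficients come from OLS on
    quasi-demeaned data; standard errors are cluster-robust by individual.

    ``variance_components=(sigma_alpha2, sigma_u2)`` bypasses the component
    estimation and runs GLS at the given values (used by equivalence checks
    against a direct block-covariance solve).
    """
    if isinstance(X, pd.DataFrame):
        design_columns = tuple(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        design_columns = tuple(
            design_columns
            if design_columns is not None
            else [f"x{i}" for i in range(Xv.shape[1])]
        )
    exp_v = np.asarray(expenditure, dtype=float)
    if np.any(exp_v <= 0):
        raise DegenerateOutcomeError("expenditures must be strictly positive")
    yv = np.log(exp_v)
    gc = _as_groups(groups)
    n_groups = int(gc.max()) + 1
    n_obs, k = Xv.shape
    if n_obs <= k:
        raise DegenerateOutcomeError(
            f"{n_obs} observations cannot identify {k} parameters"
        )
    T = np.bincount(gc).astype(float)
    Xm = np.vstack([np.bincount(gc, weights=Xv[:, j]) for j in range(k)]).T / T[:, None]
    ym = np.bincount(gc, weights=yv) / T

    if variance_components is not None:
        sigma_a2, sigma_u2 = (float(v) for v in variance_components)
    else:
        # within (fixed-effects) regression -> residual variance sigma_u^2
        Xw = Xv - Xm[gc]
        yw = yv - ym[gc]
        bw, _, rank_w, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        # demeaning zeroes the constant and any time-invariant column, so
        # rank_w already counts only the time-varying regressors
        ssr_w = float(np.sum((yw - Xw @ bw) ** 2))
        dof_w = n_obs - n_groups - rank_w
        sigma_u2 = ssr_w / max(dof_w, 1)

        # between regression on group means -> sigma_alpha^2 (Swamy-Arora)
        bb, _, rank_b, _ = np.linalg.lstsq(Xm, ym, rcond=None)
        ssr_b = float(np.sum((ym - Xm @ bb) ** 2))
        dof_b = n_groups - rank_b
        t_harm = n_groups / np.sum(1.0 / T)
        sigma_a2 = ssr_b / max(dof_b, 1) - sigma_u2 / t_harm
        if sigma_a2 < 0:
            logger.info("between variance estimate %.3g clamped to 0", sigma_a2)
            sigma_a2 = 0.0

    # quasi-demeaning FGLS
    theta_i = 1.0 - np.sqrt(sigma_u2 / (T * sigma_a2 + sigma_u2))
    Xs = Xv - theta_i[gc, None] * Xm[gc]
    ys = yv - theta_i[gc] * ym[gc]
    XtX = Xs.T @ Xs
    # pinv handles empty design cells (e.g. an interaction level absent among
    # users): the unidentified coefficient is pinned at 0, mirroring a drop
    bread = np.linalg.pinv(XtX, hermitian=True)
    beta = bread @ (Xs.T @ ys)
    resid_s = ys - Xs @ beta
    if cluster_robust:
        meat = np.zeros((k, k))
        for g in range(n_groups):
            idx = gc == g
            sg = Xs[idx].T @ resid_s[idx]
            meat += np.outer(sg, sg)
        c = (n_groups / (n_groups - 1)) * ((n_obs - 1) / max(n_obs - k, 1))
        cov = c * bread @ meat @ bread
    else:
        sigma2 = float(resid_s @ resid_s) / max(n_obs - k, 1)
        cov = sigma2 * bread
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    # Duan smearing factor from level residuals (alpha + u combined)
    resid_level = yv - Xv @ beta
    smear = float(np.mean(np.exp(resid_level)))

    return REFit(
        model="re_gls",
        coefficients={c: float(b) for c, b in zip(design_columns, beta)},
        std_errors={c: float(s) for c, s in zip(design_columns, se)},
        sigma_alpha=float(np.sqrt(sigma_a2)),
        sigma_u=float(np.sqrt(sigma_u2)),
        log_likelihood=None,
        n_obs=n_obs,
        n_individuals=n_groups,
        converged=True,
        iterations=1,
        smearing_factor=smear,
        design_columns=design_columns,
    )
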