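"""Mixed-effects logistic regression with crossed random intercepts.

Fits the model

    y_ij ~ Bernoulli( logit^-1( x_ij' beta + u_{p(ij)} + v_{i(ij)} ) ),
    u_p ~ N(0, sigma_p^2),  v_i ~ N(0, sigma_i^2)  (crossed, independent)

by maximum likelihood under the Laplace approximation to the integral over
the random effects — the same approximation lme4's ``glmer`` uses by
default, so estimates, log-likelihood and AIC are comparable with that
reference.

The marginal log-likelihood is approximated as

    l(beta, theta) ~= loglik(u_hat) - 1/2 u_hat' D^-1 u_hat
                      - 1/2 log|D| - 1/2 log|Z'WZ + D^-1|

where u_hat is the joint posterior mode of the random effects (found by
penalised Newton iteration with step halving) and W the Bernoulli weight
matrix at the mode.  The outer optimisation over (beta, log variances)
uses L-BFGS-B with finite-difference gradients; Wald standard errors come
from the finite-difference Hessian of the approximate deviance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .errors import ConvergenceError, SeparationError

_LOG_VAR_MIN = np.log(1e-8)
_LOG_VAR_MAX = np.log(100.0)


@dataclass
class CrossedLogitFit:
    """Raw estimation output; field names follow the design matrix order."""

    beta: np.ndarray
    beta_se: np.ndarray
    variances: dict[str, float]
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    message: str


def _factor_codes(labels) -> tuple[np.ndarray, int]:
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes.astype(np.intp), len(uniq)


class _Workspace:
    """Per-fit state: design, factor indexing, warm-started random modes."""

    def __init__(self, y, X, factors: dict[str, np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n = self.y.size
        self.names = list(factors)
        self.codes = []
        self.sizes = []
        for name in self.names:
            codes, size = _factor_codes(factors[name])
            self.codes.append(codes)
            self.sizes.append(size)
        self.offsets = np.concatenate(([0], np.cumsum(self.sizes)))
        self.q = int(self.offsets[-1])
        self.u = np.zeros(self.q)  # warm start across outer iterations

    def eta(self, beta, u):
        eta = self.X @ beta
        for k, codes in enumerate(self.codes):
            eta = eta + u[self.offsets[k] + codes]
        return eta

    def zt(self, vec):
        """Z' vec for the stacked random-effect design."""
        out = np.empty(self.q)
        for k, codes in enumerate(self.codes):
            out[self.offsets[k] : self.offsets[k + 1]] = np.bincount(
                codes, weights=vec, minlength=self.sizes[k]
            )
        return out

    def ztwz(self, w):
        """Dense Z' W Z (q x q) from per-row weights."""
        H = np.zeros((self.q, self.q))
        for k, codes_k in enumerate(self.codes):
            dk = np.bincount(codes_k, weights=w, minlength=self.sizes[k])
            sl_k = slice(self.offsets[k], self.offsets[k + 1])
            H[sl_k, sl_k] += np.diag(dk)
            for m in range(k + 1, len(self.codes)):
                codes_m = self.codes[m]
                block = np.zeros((self.sizes[k], self.sizes[m]))
                np.add.at(block, (codes_k, codes_m), w)
                sl_m = slice(self.offsets[m], self.offsets[m + 1])
                H[sl_k, sl_m] += block
                H[sl_m, sl_k] += block.T
        return H

    def prec_diag(self, variances):
        """Diagonal of D^-1 for per-factor variances."""
        prec = np.empty(self.q)
        for k, var in enumerate(variances):
            prec[self.offsets[k] : self.offsets[k + 1]] = 1.0 / var
        return prec


def _penalized_loglik(ws, y, eta, u, prec):
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * np.sum(prec * u * u))


def _inner_mode(ws: _Workspace, beta, variances, tol=1e-10, max_iter=60):
    """Posterior mode of the random effects by penalised Newton iteration."""
    prec = ws.prec_diag(variances)
    u = ws.u.copy()
    eta = ws.eta(beta, u)
    obj = _penalized_loglik(ws, ws.y, eta, u, prec)
    chol = None
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = ws.zt(ws.y - mu) - prec * u
        if np.max(np.abs(grad)) < tol:
            break
        H = ws.ztwz(w)
        H[np.diag_indices_from(H)] += prec
        chol = linalg.cho_factor(H, lower=True)
        step = linalg.cho_solve(chol, grad)
        # step-halving on the penalised objective
        scale = 1.0
        for _ in range(30):
            u_new = u + scale * step
            eta_new = ws.eta(beta, u_new)
            obj_new = _penalized_loglik(ws, ws.y, eta_new, u_new, prec)
            if obj_new >= obj - 1e-12:
                break
            scale *= 0.5
        u, eta, obj = u_new, eta_new, obj_new
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = ws.ztwz(w)
    H[np.diag_indices_from(H)] += prec
    chol = linalg.cho_factor(H, lower=True)
    ws.u = u  # warm start the next outer evaluation
    return u, eta, chol, prec


def _laplace_nll(ws: _Workspace, params, n_fixed):
    beta = params[:n_fixed]
    variances = np.exp(params[n_fixed:])
    u, eta, chol, prec = _inner_mode(ws, beta, variances)
    logdet_h = 2.0 * np.sum(np.log(np.diag(chol[0])))
    logdet_d = float(
        sum(size * lv for size, lv in zip(ws.sizes, params[n_fixed:]))
    )
    ll = (
        _penalized_loglik(ws, ws.y, eta, u, prec)
        - 0.5 * logdet_d
        - 0.5 * logdet_h
    )
    return -ll


def _numeric_hessian(fun, x, step=1e-4):
    n = x.size
    H = np.empty((n, n))
    hs = step * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = hs[i]
            ej[j] = hs[j]
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * hs[i] * hs[j])
    return H


def fit_crossed_logit(
    y,
    X,
    factors: dict[str, np.ndarray],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> CrossedLogitFit:
    """Fit the crossed random-intercept logistic model.

    Parameters
    ----------
    y : binary outcome vector (0/1).
    X : fixed-effect design matrix, first column the intercept.
    factors : mapping factor name -> per-row level labels; one random
        intercept per factor, variances estimated on the log scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError(
            "outcome is constant; the logistic model is not estimable"
        )
    for name, labels in factors.items():
        if len(np.unique(np.asarray(labels))) < 2:
            raise ValueError(f"random factor {name!r} needs >= 2 levels")
    ws = _Workspace(y, X, factors)
    n_fixed = X.shape[1]

    # start beta at the ordinary logistic ML fit, variances at 0.5
    beta0 = _start_beta(y, X)
    x0 = np.concatenate([beta0, np.full(len(ws.names), np.log(0.5))])
    bounds = [(-30.0, 30.0)] * n_fixed + [(_LOG_VAR_MIN, _LOG_VAR_MAX)] * len(ws.names)

    nll = lambda p: _laplace_nll(ws, p, n_fixed)
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-6, "eps": 1e-6},
    )
    params = res.x
    loglik = -float(res.fun)

    hess = _numeric_hessian(nll, params)
    beta_se = np.full(n_fixed, np.nan)
    se_ok = False
    try:
        cov = linalg.inv(hess)
        diag = np.diag(cov)[:n_fixed]
        if np.all(diag > 0):
            beta_se = np.sqrt(diag)
            se_ok = True
    except linalg.LinAlgError:
        pass
    if not se_ok:  # fall back to pseudo-inverse on a near-singular Hessian
        cov = np.linalg.pinv(hess)
        diag = np.abs(np.diag(cov)[:n_fixed])
        beta_se = np.sqrt(diag)

    n_params = n_fixed + len(ws.names)
    variances = {
        name: float(np.exp(lv))
        for name, lv in zip(ws.names, params[n_fixed:])
    }
    converged = bool(res.success) and se_ok
    return CrossedLogitFit(
        beta=params[:n_fixed].copy(),
        beta_se=beta_se,
        variances=variances,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        n_obs=int(y.size),
        n_params=n_params,
        converged=converged,
        message=str(res.message),
    )


def _start_beta(y, X):
    """Ordinary logistic regression starting values (few Newton steps)."""
    n, p = X.shape
    beta = np.zeros(p)
    mean = np.clip(y.mean(), 1e-3, 1 - 1e-3)
    beta[0] = np.log(mean / (1.0 - mean))
    for _ in range(25):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < 1e-8:
            break
        H = (X * w[:, None]).T @ X
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise SeparationError(
                "logistic starting fit is singular (quasi-separation?)"
            ) from exc
        if np.max(np.abs(step)) > 10.0:  # cap steps under near-separation
            step *= 10.0 / np.max(np.abs(step))
        beta = beta + step
    if not np.all(np.isfinite(beta)):
        raise ConvergenceError("non-finite starting values for the mixed logit")
    return beta
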