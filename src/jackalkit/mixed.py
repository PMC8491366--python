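"""Weighted logistic regression with individual random effects (Laplace approximation).

The used--available habitat model treats each animal as a group with a random
intercept and, optionally, random slopes on the covariates. Following current
practice for used--available designs, the random-intercept variance is FIXED
at a large constant (default 1e6) rather than estimated — the per-animal
intercepts absorb each animal's used:available sampling ratio and must not be
shrunk — while the random-slope variances are estimated. Available points
carry a large weight so the logistic fit approximates the underlying
inhomogeneous-point-process likelihood.

Estimation maximizes the Laplace-approximated marginal likelihood: an inner
Newton solve finds each group's random-effect mode, and the outer optimization
runs over the fixed effects and log slope variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["MixedLogisticFit", "fit_mixed_logistic"]


@dataclass
class MixedLogisticFit:
    """Result of a Laplace mixed-logistic fit."""

    beta: np.ndarray            # intercept first, then covariates
    se: np.ndarray              # Wald SEs, same layout
    slope_variances: np.ndarray  # estimated variance per random slope
    intercept_variance: float   # the fixed constant
    random_modes: dict          # group -> mode of the random effects
    loglik: float
    converged: bool
    n_groups: int


def _group_neg_hessian(Z: np.ndarray, w: np.ndarray, pi: np.ndarray) -> np.ndarray:
    W = w * pi * (1.0 - pi)
    return (Z * W[:, None]).T @ Z


def _inner_mode(
    eta_fixed: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    d_inv: np.ndarray,
    u0: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Newton ascent of the penalized group log-likelihood; returns (û, value, Hessian)."""

    def value(u: np.ndarray) -> float:
        eta = eta_fixed + Z @ u
        # numerically safe log-likelihood: -w * log(1 + exp(-(2y-1) eta))
        s = (2.0 * y - 1.0) * eta
        ll = -np.sum(w * np.logaddexp(0.0, -s))
        return ll - 0.5 * float(u @ (d_inv * u))

    u = u0.copy()
    f = value(u)
    for _ in range(max_iter):
        eta = eta_fixed + Z @ u
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = Z.T @ (w * (y - pi)) - d_inv * u
        H = _group_neg_hessian(Z, w, pi) + np.diag(d_inv)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(H)
        # backtracking line search
        t = 1.0
        for _ in range(30):
            u_new = u + t * step
            f_new = value(u_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        if f_new < f:
            break
        gain = f_new - f
        u, f = u_new, f_new
        if abs(gain) < tol * (1.0 + abs(f)):
            break
    eta = eta_fixed + Z @ u
    pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    H = _group_neg_hessian(Z, w, pi) + np.diag(d_inv)
    return u, f, H


def _laplace_negll(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    group_idx: list[np.ndarray],
    n_fixed: int,
    n_slopes: int,
    slope_cols: np.ndarray,
    intercept_variance: float,
    mode_cache: dict,
) -> float:
    beta = params[:n_fixed]
    log_var = params[n_fixed:]
    d = np.concatenate(([intercept_variance], np.exp(log_var)))
    d_inv = 1.0 / d
    eta_all = X @ beta
    total = 0.0
    for g, idx in enumerate(group_idx):
        Z = np.column_stack([np.ones(len(idx)), X[idx][:, slope_cols]]) if n_slopes else np.ones(
            (len(idx), 1)
        )
        u0 = mode_cache.get(g, np.zeros(1 + n_slopes))
        u, f, H = _inner_mode(eta_all[idx], Z, y[idx], w[idx], d_inv, u0)
        mode_cache[g] = u
        sign, logdet = np.linalg.slogdet(H * d[None, :])
        # log det(D H) ... Laplace correction is -1/2 log det(H D + I); using
        # H formed with the penalty already included: det(H_pen D) = det(H_data D + I)
        total += f - 0.5 * logdet
    return -total


def fit_mixed_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    groups: np.ndarray,
    random_slopes: bool = True,
    intercept_variance: float = 1e6,
    beta_start: np.ndarray | None = None,
) -> MixedLogisticFit:
    """Fit the weighted mixed logistic model by Laplace-approximated ML.

    ``X`` holds the covariates WITHOUT an intercept column (one is added);
    ``groups`` labels the individuals. With ``random_slopes`` every covariate
    gets a random slope whose variance is estimated; the random intercept
    variance stays fixed at ``intercept_variance``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups (animals) for random effects")
    group_idx = [np.flatnonzero(labels == g) for g in uniq]

    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    n_fixed = p + 1
    n_slopes = p if random_slopes else 0
    slope_cols = 1 + np.arange(p)  # columns of Xd used for random slopes

    if beta_start is None:
        beta_start = np.zeros(n_fixed)
    theta_start = np.full(n_slopes, np.log(0.1))
    x0 = np.concatenate([beta_start, theta_start])
    mode_cache: dict = {}

    def objective(params: np.ndarray) -> float:
        return _laplace_negll(
            params, Xd, y, w, group_idx, n_fixed, n_slopes, slope_cols,
            intercept_variance, mode_cache,
        )

    bounds = [(None, None)] * n_fixed + [(np.log(1e-8), np.log(1e4))] * n_slopes
    # the finite-difference step must dominate the inner-solve noise, hence eps
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9, "eps": 1e-6},
    )
    beta_hat = res.x[:n_fixed]
    slope_var = np.exp(res.x[n_fixed:]) if n_slopes else np.array([])

    # Wald SEs from a numerical Hessian of the profile objective over beta
    def beta_obj(b: np.ndarray) -> float:
        return objective(np.concatenate([b, res.x[n_fixed:]]))

    H = _numerical_hessian(beta_obj, beta_hat)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_fixed, np.nan)

    if not res.success:
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        raise RuntimeError(
            f"mixed-model optimization did not converge (max |grad| = {grad_norm:.3g})"
        )

    modes = {g: mode_cache.get(i, np.zeros(1 + n_slopes)) for i, g in enumerate(uniq)}
    return MixedLogisticFit(
        beta=beta_hat,
        se=se,
        slope_variances=slope_var,
        intercept_variance=intercept_variance,
        random_modes=modes,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_groups=len(uniq),
    )


def _numerical_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    k = len(x)
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                f1 = fun(x + ei)
                f2 = fun(x - ei)
                H[i, i] = (f1 - 2 * f0 + f2) / h[i] ** 2
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H
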