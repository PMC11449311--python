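"""Estimation engines for habitat-selection models.

Two mixed-model devices are implemented, mirroring how used/available designs
are fitted in practice:

* the *Poisson formulation* of conditional logistic regression for step
  selection: one intercept per stratum treated as a Gaussian random effect
  whose variance is fixed large (10^3), which conditions the strata out while
  permitting additional random slopes;
* the *weighted logistic* trick for resource selection: available points get
  a large weight (1000) so the Bernoulli fit approximates the inhomogeneous
  point-process likelihood, with a per-animal random intercept of fixed
  variance 10^3.

Both are fitted by penalized Newton iterations on the joint (fixed effect,
random effect) objective; random effects are integrated by the Laplace
approximation, and free random-slope variances are optimized on the Laplace
marginal likelihood.  An exact conditional-logistic Newton maximizer is
provided as an independent oracle for the Poisson formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

MAX_ITER = 200
REL_TOL = 1e-10
SEPARATION_NORM = 30.0


@dataclass
class _JointFit:
    theta: np.ndarray  # dense parameters (fixed effects first, then random cols)
    alpha: np.ndarray | None  # stratum intercepts (Poisson path) or None
    vcov_theta: np.ndarray  # inverse Schur complement over the dense block
    loglik_data: float  # unpenalized data log-likelihood at the mode
    loglik_marginal: float  # Laplace marginal log-likelihood
    converged: bool
    flags: list = field(default_factory=list)
    n_iter: int = 0


def _check_full_rank(X: np.ndarray) -> None:
    if X.size and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


# ---------------------------------------------------------------------------
# Poisson formulation with stratum intercepts
# ---------------------------------------------------------------------------

def fit_poisson_strata(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    penalty: np.ndarray,
    sigma2_strata: float = 1e3,
    n_fixed: int | None = None,
    max_iter: int = MAX_ITER,
    tol: float = REL_TOL,
) -> _JointFit:
    """Penalized Poisson fit with one intercept per stratum.

    ``X`` holds the dense columns (fixed effects, then any random-slope
    columns) with diagonal ``penalty`` (0 for fixed effects, 1/tau^2 for
    random columns).  Stratum intercepts are profiled through a Schur
    complement, so the per-iteration cost is linear in rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    codes = np.unique(strata, return_inverse=True)[1]
    S = codes.max() + 1
    n, q = X.shape
    n_fixed = q if n_fixed is None else n_fixed
    _check_full_rank(X[:, :n_fixed])
    theta = np.zeros(q)
    alpha = np.zeros(S)
    pen = np.asarray(penalty, dtype=float)
    inv_s2 = 1.0 / sigma2_strata

    def objective(theta, alpha):
        eta = X @ theta + alpha[codes]
        mu = np.exp(np.clip(eta, -700, 700))
        ll = float(y @ eta - mu.sum())
        return ll - 0.5 * float(pen @ (theta**2)) - 0.5 * inv_s2 * float(alpha @ alpha)

    obj = objective(theta, alpha)
    converged = False
    flags: list = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ theta + alpha[codes]
        mu = np.exp(np.clip(eta, -700, 700))
        resid = y - mu
        g_theta = X.T @ resid - pen * theta
        g_alpha = np.bincount(codes, weights=resid, minlength=S) - inv_s2 * alpha
        D = np.bincount(codes, weights=mu, minlength=S) + inv_s2
        C = np.empty((S, q))  # C[s, j] = sum_{i in s} mu_i X_ij
        for j in range(q):
            C[:, j] = np.bincount(codes, weights=mu * X[:, j], minlength=S)
        A = (X * mu[:, None]).T @ X + np.diag(pen)
        schur = A - (C / D[:, None]).T @ C
        rhs = g_theta - C.T @ (g_alpha / D)
        try:
            d_theta = np.linalg.solve(schur, rhs)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        d_alpha = (g_alpha - C @ d_theta) / D
        # backtracking line search on the penalized objective
        step = 1.0
        for _ in range(40):
            cand = objective(theta + step * d_theta, alpha + step * d_alpha)
            if cand >= obj - 1e-12:
                break
            step *= 0.5
        theta = theta + step * d_theta
        alpha = alpha + step * d_alpha
        new_obj = objective(theta, alpha)
        if abs(new_obj - obj) <= tol * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if np.linalg.norm(theta[:n_fixed]) > SEPARATION_NORM:
        flags.append("separation_suspected")
        converged = False

    # recompute curvature pieces at the mode
    eta = X @ theta + alpha[codes]
    mu = np.exp(np.clip(eta, -700, 700))
    D = np.bincount(codes, weights=mu, minlength=S) + inv_s2
    C = np.empty((S, q))
    for j in range(q):
        C[:, j] = np.bincount(codes, weights=mu * X[:, j], minlength=S)
    A = (X * mu[:, None]).T @ X + np.diag(pen)
    schur = A - (C / D[:, None]).T @ C
    vcov = np.linalg.inv(schur)
    ll_data = float(y @ eta - mu.sum())  # y in {0,1} so log y! = 0

    # Laplace marginal: integrate stratum intercepts and penalized columns
    rand = pen > 0
    ll_marg = ll_data - 0.5 * inv_s2 * float(alpha @ alpha) - 0.5 * S * np.log(sigma2_strata)
    ll_marg -= 0.5 * float(np.log(D).sum())
    if rand.any():
        ll_marg -= 0.5 * float((pen[rand] * theta[rand] ** 2).sum())
        ll_marg += 0.5 * float(np.log(pen[rand]).sum())  # -1/2 log tau^2 per column
        idx = np.where(rand)[0]
        block = A[np.ix_(idx, idx)] - (C[:, idx] / D[:, None]).T @ C[:, idx]
        sign, logdet = np.linalg.slogdet(block)
        ll_marg -= 0.5 * logdet if sign > 0 else np.inf
    return _JointFit(theta, alpha, vcov, ll_data, ll_marg, converged, flags, it)


# ---------------------------------------------------------------------------
# Weighted logistic with random effects (RSF)
# ---------------------------------------------------------------------------

def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    penalty: np.ndarray,
    n_fixed: int | None = None,
    max_iter: int = MAX_ITER,
    tol: float = REL_TOL,
) -> _JointFit:
    """Penalized Newton fit of a weighted Bernoulli likelihood.

    Columns with ``penalty > 0`` are random effects (per-animal intercepts
    and slopes); the Laplace marginal integrates them out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    pen = np.asarray(penalty, dtype=float)
    n, q = X.shape
    n_fixed = q if n_fixed is None else n_fixed
    _check_full_rank(X[:, :n_fixed])
    theta = np.zeros(q)

    def objective(theta):
        eta = X @ theta
        ll = float(w @ (y * eta - np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(pen @ (theta**2))

    obj = objective(theta)
    converged = False
    flags: list = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ theta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        g = X.T @ (w * (y - p)) - pen * theta
        wvar = w * p * (1.0 - p)
        H = (X * wvar[:, None]).T @ X + np.diag(pen)
        try:
            d = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        step = 1.0
        for _ in range(40):
            cand = objective(theta + step * d)
            if cand >= obj - 1e-12:
                break
            step *= 0.5
        theta = theta + step * d
        new_obj = objective(theta)
        if abs(new_obj - obj) <= tol * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if np.linalg.norm(theta[:n_fixed]) > SEPARATION_NORM:
        flags.append("separation_suspected")
        converged = False

    eta = X @ theta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    wvar = w * p * (1.0 - p)
    H = (X * wvar[:, None]).T @ X + np.diag(pen)
    Hinv = np.linalg.inv(H)
    ll_data = float(w @ (y * eta - np.logaddexp(0.0, eta)))
    rand = pen > 0
    ll_marg = ll_data
    if rand.any():
        idx = np.where(rand)[0]
        fix = np.where(~rand)[0]
        ll_marg -= 0.5 * float((pen[rand] * theta[rand] ** 2).sum())
        ll_marg += 0.5 * float(np.log(pen[rand]).sum())
        Huu = H[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(Huu)
        ll_marg -= 0.5 * logdet if sign > 0 else np.inf
        # vcov of fixed effects: corresponding block of the full inverse
        vcov = Hinv[np.ix_(fix, fix)]
    else:
        vcov = Hinv
    return _JointFit(theta, None, Hinv, ll_data, ll_marg, converged, flags, it)


# ---------------------------------------------------------------------------
# Exact conditional logistic (the oracle)
# ---------------------------------------------------------------------------

def fit_clogit_newton(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-12,
):
    """Maximize the exact conditional likelihood
    prod_s exp(beta'x_used) / sum_j exp(beta'x_j) by Newton iteration.

    Returns (beta, vcov, loglik, converged, flags).  Perfect separation (a
    direction along which the used point dominates every stratum) shows up as
    a diverging ``beta`` and is flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    order = np.argsort(strata, kind="stable")
    X, y, strata = X[order], y[order], strata[order]
    codes = np.unique(strata, return_inverse=True)[1]
    S = codes.max() + 1
    n, q = X.shape
    _check_full_rank(X)
    beta = np.zeros(q)
    flags: list = []
    converged = False

    def parts(beta):
        eta = X @ beta
        emax = np.full(S, -np.inf)
        np.maximum.at(emax, codes, eta)
        w = np.exp(eta - emax[codes])
        denom = np.bincount(codes, weights=w, minlength=S)
        prob = w / denom[codes]
        ll = float(y @ eta - (np.log(denom) + emax).sum())
        return prob, ll

    prob, ll = parts(beta)
    for _ in range(max_iter):
        xbar = np.empty((S, q))
        for j in range(q):
            xbar[:, j] = np.bincount(codes, weights=prob * X[:, j], minlength=S)
        g = X.T @ y - xbar.sum(axis=0)
        H = (X * prob[:, None]).T @ X - xbar.T @ xbar
        try:
            d = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        step = 1.0
        for _ in range(40):
            _, cand = parts(beta + step * d)
            if cand >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * d
        prob, new_ll = parts(beta)
        if np.linalg.norm(beta) > SEPARATION_NORM:
            flags.append("separation_suspected")
            break
        if abs(new_ll - ll) <= tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    xbar = np.empty((S, q))
    for j in range(q):
        xbar[:, j] = np.bincount(codes, weights=prob * X[:, j], minlength=S)
    H = (X * prob[:, None]).T @ X - xbar.T @ xbar
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((q, q), np.nan)
    return beta, vcov, ll, converged, flags


# ---------------------------------------------------------------------------
# Laplace optimization of free random-slope variances
# ---------------------------------------------------------------------------

def optimize_variances(marginal_fn, n_var: int, start_log_var: float = 0.0, maxiter: int = 120):
    """Maximize a Laplace marginal likelihood over log-variances.

    ``marginal_fn(variances) -> loglik_marginal``.  Returns the optimal
    variance vector and the achieved marginal log-likelihood.
    """

    def neg(logv):
        v = np.exp(np.clip(logv, -12.0, 8.0))
        ll = marginal_fn(v)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(
        neg,
        np.full(n_var, start_log_var),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": maxiter * max(n_var, 1)},
    )
    v = np.exp(np.clip(res.x, -12.0, 8.0))
    return v, -res.fun
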