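"""Restricted maximum likelihood machinery.

Two solvers live here:

* :func:`reml_variance_components` — generic multi-component REML for the
  plot-level mixed models (genotype / block / genotype-x-environment random
  effects).  The covariance is built explicitly, which is comfortably fast at
  trial sizes (a few hundred to ~1000 plots).  Components are bounded at
  zero, so negative solutions are clamped rather than reported.

* :func:`kernel_reml` — single-kernel mixed model y = Xb + g + e with
  var(g) = s2_g * K, profiled over the variance ratio on the eigenbasis of K
  (the classic efficient exact scheme for genomic BLUP / ridge models).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, optimize

_LOG2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class RemlResult:
    variances: np.ndarray      # one per random factor, error variance last
    loglik: float
    beta: np.ndarray           # GLS fixed-effect estimates
    converged: bool
    clamped: np.ndarray        # True where a component sits on the zero bound


def _neg_reml_ll(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                 ZZt: list[np.ndarray]) -> float:
    n = y.size
    V = theta[-1] * np.eye(n)
    for s2, K in zip(theta[:-1], ZZt):
        V += s2 * K
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return 1e10
    logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = linalg.cho_solve(cf, X)
    Vi_y = linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e10
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = r @ linalg.cho_solve(cf, r)
    p = X.shape[1]
    return 0.5 * (logdet_V + logdet_XtViX + quad + (n - p) * _LOG2PI)


def reml_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    tol: float = 1e-8,
) -> RemlResult:
    """Fit y = X beta + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I).

    Returns variance components ordered as ``Z_list`` with the error variance
    appended.  Components are constrained to [0, inf); a component that ends
    within numerical distance of zero is flagged as clamped.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    vy = float(np.var(y))
    if vy == 0.0:
        k = len(Z_list) + 1
        return RemlResult(np.zeros(k), 0.0, np.zeros(X.shape[1]), True,
                          np.ones(k, bool))
    # work on the unit-variance scale for conditioning
    sd = np.sqrt(vy)
    ys = y / sd
    ZZt = [Z @ Z.T for Z in Z_list]
    k = len(Z_list) + 1
    x0 = np.full(k, 1.0 / k)
    bounds = [(0.0, 10.0)] * k
    res = optimize.minimize(
        _neg_reml_ll, x0, args=(ys, X, ZZt), method="L-BFGS-B",
        bounds=bounds, options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 1000},
    )
    # derivative-free polish (the likelihood is cheap at these sizes)
    polish = optimize.minimize(
        _neg_reml_ll, res.x, args=(ys, X, ZZt), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    if polish.fun <= res.fun:
        res = polish
    theta = np.maximum(res.x, 0.0) * vy
    clamped = theta <= 1e-10 * vy
    theta[clamped] = 0.0
    # recompute GLS beta at the solution
    n = y.size
    V = max(theta[-1], 1e-12 * vy) * np.eye(n)
    for s2, K in zip(theta[:-1], ZZt):
        V += s2 * K
    cf = linalg.cho_factor(V, lower=True)
    Vi_X = linalg.cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ linalg.cho_solve(cf, y))
    return RemlResult(theta, -res.fun, beta, bool(res.success), clamped)


# ---------------------------------------------------------------------------
# Single-kernel REML (efficient exact scheme)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class KernelRemlResult:
    s2_g: float
    s2_e: float
    beta: np.ndarray
    g_train: np.ndarray       # BLUP genetic values for training records
    loglik: float
    # cached pieces for cross-block prediction
    _Vinv_r: np.ndarray = None  # V^{-1} (y - X beta)


def kernel_reml(K: np.ndarray, y: np.ndarray, X: np.ndarray | None = None
                ) -> KernelRemlResult:
    """Exact REML for y = X b + g + e, var(g) = s2_g K, var(e) = s2_e I.

    Profiles the REML log-likelihood over the ratio s2_e / s2_g on the
    eigenbasis of K.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]

    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.maximum(w, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)          # delta = s2_e / s2_g
        d = w + delta                       # V = s2_g * U diag(d) U'
        Xd = Xt / d[:, None]
        XtViX = Xt.T @ Xd
        try:
            beta = np.linalg.solve(XtViX, Xd.T @ yt)
        except np.linalg.LinAlgError:
            return 1e10
        r = yt - Xt @ beta
        quad = np.sum(r * r / d)
        s2_g = quad / (n - p)
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0 or s2_g <= 0:
            return 1e10
        return 0.5 * ((n - p) * np.log(s2_g) + np.sum(np.log(d))
                      + logdet_XtViX + (n - p) * (1.0 + _LOG2PI))

    grid = np.linspace(np.log(1e-6), np.log(1e6), 60)
    vals = np.array([neg_ll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    opt = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    log_delta = float(opt.x)
    delta = np.exp(log_delta)
    d = w + delta
    Xd = Xt / d[:, None]
    XtViX = Xt.T @ Xd
    beta = np.linalg.solve(XtViX, Xd.T @ yt)
    r = yt - Xt @ beta
    s2_g = float(np.sum(r * r / d) / (n - p))
    s2_e = float(delta * s2_g)
    # BLUP of g: s2_g K V^{-1} (y - X beta); V^{-1} z = U diag(1/(s2_g d)) U' z
    Vinv_r = U @ (r / (s2_g * d))
    g_train = s2_g * (K @ Vinv_r)
    return KernelRemlResult(s2_g, s2_e, beta, g_train, -float(opt.fun), Vinv_r)


def kernel_predict(res: KernelRemlResult, K_cross: np.ndarray,
                   X_new: np.ndarray | None = None) -> np.ndarray:
    """Predict new records from a fitted kernel model.

    ``K_cross`` is the (n_new, n_train) kernel block between new and training
    lines; the genetic BLUP for new lines is s2_g * K_cross @ V^{-1} residual.
    """
    g_new = res.s2_g * (K_cross @ res._Vinv_r)
    if X_new is None:
        X_new = np.ones((K_cross.shape[0], 1))
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    return X_new @ res.beta + g_new
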