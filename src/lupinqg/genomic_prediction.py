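"""Whole-genome regression models and cross-validation protocols.

Four models predict line BLUPs from genome-wide SNP dosages:

* rrBLUP — ridge regression with the ridge parameter lambda = s2_e / s2_q
  estimated by exact REML on the equivalent mixed model (profiled on the
  eigenbasis of W W'); equivalent to GBLUP with the VanRaden kinship up to
  the kinship scaling, which serves as a numerical oracle in the tests.
* Bayesian Lasso — double-exponential marker priors, Gibbs-sampled
  (Park-Casella scale-mixture representation; numba inner loop).
* RKHS / GBLUP — Gibbs sampler with the VanRaden genomic relationship matrix
  G = M M' / [2 sum p_i (1 - p_i)] as the covariance kernel.
* WGBLUP — GBLUP on a weighted kinship G* = M D M' / [2 sum p_i (1 - p_i)]
  where the marker weights derive from GWAS p-values computed on the
  training partition only; a structural guard raises if weight provenance
  includes validation lines.

Predictive ability is the Pearson correlation of predicted vs observed
held-out values, under 10-fold cross-validation (repeated) or a
cross-environment protocol (train on one environment's BLUPs, validate on
the other's, over held-out lines).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numba import njit

from ._reml import kernel_reml, kernel_predict
from .gwas_scan import association_scan
from .containers import GenotypeMatrix

MODELS = ("rrBLUP", "BL", "RKHS", "WGBLUP")


class LeakageError(RuntimeError):
    """Raised when training-fold-only information touches validation lines."""


@dataclasses.dataclass
class GsModelSpec:
    model: str = "rrBLUP"
    include_structure: bool = False
    missing_rate_preset: float = 0.30
    gibbs_iterations: int = 10_000
    gibbs_burn_in: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.gibbs_burn_in >= self.gibbs_iterations:
            raise ValueError("burn_in must be < iterations")


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship_vanraden(W_raw: np.ndarray, weights: np.ndarray | None = None,
                     jitter: float = 1e-8) -> np.ndarray:
    """VanRaden genomic relationship matrix, optionally marker-weighted.

    G = M D M' / [2 sum p_i (1 - p_i)] with M the dosage matrix centered at
    twice the observed allele frequency and D a diagonal of non-negative
    marker weights (identity by default).  Zero-variance columns are
    excluded; the result is symmetrized and jittered to PSD if needed.
    """
    W = np.asarray(W_raw, float)
    if np.isnan(W).any():
        raise ValueError("kinship requires complete dosages")
    p = W.mean(axis=0) / 2.0
    keep = W.std(axis=0) > 0
    if not keep.any():
        raise ValueError("no polymorphic markers for kinship")
    M = W[:, keep] - 2.0 * p[keep]
    denom = 2.0 * np.sum(p[keep] * (1.0 - p[keep]))
    if weights is None:
        G = M @ M.T / denom
    else:
        d = np.asarray(weights, float)[keep]
        if (d < 0).any():
            raise ValueError("kinship weights must be non-negative")
        G = (M * d) @ M.T / denom
    G = (G + G.T) / 2.0
    wmin = np.linalg.eigvalsh(G)[0]
    if wmin < -1e-10:
        G = G + (jitter - wmin) * np.eye(G.shape[0])
    return G


def pvalue_weights(pvalues: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Marker weights d_i = -log10(p_i), normalized to mean 1, floored."""
    p = np.clip(np.asarray(pvalues, float), np.finfo(float).tiny, 1.0)
    d = -np.log10(p)
    mu = d.mean()
    d = d / mu if mu > 0 else np.ones_like(d)
    return np.maximum(d, floor)


# ---------------------------------------------------------------------------
# rrBLUP (exact REML)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RrBlupFit:
    beta: np.ndarray            # fixed effects (intercept first)
    q: np.ndarray               # marker effects
    s2_q: float
    s2_e: float
    col_means: np.ndarray

    def predict(self, W_new: np.ndarray, X_new: np.ndarray | None = None) -> np.ndarray:
        Wc = np.asarray(W_new, float) - self.col_means
        n = Wc.shape[0]
        X = np.ones((n, 1)) if X_new is None else np.column_stack([np.ones(n), X_new])
        return X @ self.beta + Wc @ self.q


def fit_rrblup(W: np.ndarray, y: np.ndarray, X: np.ndarray | None = None) -> RrBlupFit:
    """Ridge-regression BLUP with REML-estimated lambda = s2_e / s2_q."""
    W = np.asarray(W, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if n < 10:
        raise ValueError("at least 10 lines required")
    if np.all(W.std(axis=0) == 0):
        raise ValueError("zero marker variance")
    col_means = W.mean(axis=0)
    Wc = W - col_means
    Xd = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    K = Wc @ Wc.T
    res = kernel_reml(K, y, Xd)
    lam = res.s2_e / res.s2_g
    r = y - Xd @ res.beta
    q = Wc.T @ np.linalg.solve(K + lam * np.eye(n), r)
    return RrBlupFit(res.beta, q, res.s2_g, res.s2_e, col_means)


def fit_gblup_reml(G: np.ndarray, y: np.ndarray, X: np.ndarray | None = None):
    """Exact-REML GBLUP on a precomputed kernel (the rrBLUP-equivalence
    oracle and a fast deterministic alternative to the Gibbs RKHS fit)."""
    n = len(y)
    Xd = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    return kernel_reml(G, y, Xd)


# ---------------------------------------------------------------------------
# Bayesian Lasso (Gibbs; Park-Casella scale mixture)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rinvgauss(mu, lam):
    v = np.random.normal()
    w = v * v
    x = mu + mu * mu * w / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w)
    if x <= 0.0:
        x = 1e-12
    if np.random.rand() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _bl_gibbs(y, W, X, iters, burn, seed, fix_sigma2, sigma2_fix,
              fix_lambda2, lambda2_fix, r_prior, delta_prior):
    n, m = W.shape
    p = X.shape[1]
    np.random.seed(seed)
    xx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        xx[j] = s
    xxX = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, k] * X[i, k]
        xxX[k] = s

    beta = np.zeros(m)
    b = np.zeros(p)
    tau2 = np.ones(m)
    vy = np.var(y)
    sigma2 = sigma2_fix if fix_sigma2 else max(vy / 2.0, 1e-8)
    lambda2 = lambda2_fix if fix_lambda2 else 1.0
    resid = y.copy()

    beta_sum = np.zeros(m)
    b_sum = np.zeros(p)
    s2_sum = 0.0
    l2_sum = 0.0
    kept = 0

    for it in range(iters):
        for k in range(p):
            old = b[k]
            dotv = 0.0
            for i in range(n):
                resid[i] += X[i, k] * old
                dotv += X[i, k] * resid[i]
            mean = dotv / xxX[k]
            b[k] = mean + np.random.normal() * np.sqrt(sigma2 / xxX[k])
            for i in range(n):
                resid[i] -= X[i, k] * b[k]
        for j in range(m):
            if xx[j] == 0.0:
                beta[j] = 0.0
                continue
            old = beta[j]
            dotv = 0.0
            for i in range(n):
                resid[i] += W[i, j] * old
                dotv += W[i, j] * resid[i]
            cj = xx[j] + 1.0 / tau2[j]
            mean = dotv / cj
            beta[j] = mean + np.random.normal() * np.sqrt(sigma2 / cj)
            for i in range(n):
                resid[i] -= W[i, j] * beta[j]
        for j in range(m):
            bj = abs(beta[j])
            if bj < 1e-10:
                bj = 1e-10
            mu = np.sqrt(lambda2 * sigma2) / bj
            inv_tau = _rinvgauss(mu, lambda2)
            tau2[j] = 1.0 / inv_tau
        if not fix_lambda2:
            rate = 0.5 * np.sum(tau2) + delta_prior
            lambda2 = np.random.gamma(m + r_prior, 1.0 / rate)
        if not fix_sigma2:
            ssr = 0.0
            for i in range(n):
                ssr += resid[i] * resid[i]
            sb = 0.0
            for j in range(m):
                sb += beta[j] * beta[j] / tau2[j]
            shape = 0.5 * (n + m)
            scale = 0.5 * (ssr + sb)
            sigma2 = scale / np.random.gamma(shape, 1.0)
        if it >= burn:
            kept += 1
            for j in range(m):
                beta_sum[j] += beta[j]
            for k in range(p):
                b_sum[k] += b[k]
            s2_sum += sigma2
            l2_sum += lambda2
    return (beta_sum / kept, b_sum / kept, s2_sum / kept, l2_sum / kept)


@dataclasses.dataclass
class BayesianLassoFit:
    beta: np.ndarray            # fixed effects (intercept first)
    q: np.ndarray               # posterior-mean marker effects
    sigma2: float
    lambda2: float
    col_means: np.ndarray

    def predict(self, W_new: np.ndarray, X_new: np.ndarray | None = None) -> np.ndarray:
        Wc = np.asarray(W_new, float) - self.col_means
        n = Wc.shape[0]
        X = np.ones((n, 1)) if X_new is None else np.column_stack([np.ones(n), X_new])
        return X @ self.beta + Wc @ self.q


def fit_bayesian_lasso(W: np.ndarray, y: np.ndarray, X: np.ndarray | None = None,
                       iterations: int = 10_000, burn_in: int = 1_000,
                       seed: int = 0, fix_sigma2: float | None = None,
                       fix_lambda2: float | None = None,
                       r_prior: float = 0.1, delta_prior: float = 0.1
                       ) -> BayesianLassoFit:
    """Gibbs-sampled Bayesian Lasso; structure covariates enter as flat-prior
    fixed effects.  Posterior means over the post-burn-in chain are returned;
    the chain is bit-reproducible under a fixed seed."""
    W = np.ascontiguousarray(np.asarray(W, float))
    y = np.asarray(y, float).ravel()
    n = y.size
    col_means = W.mean(axis=0)
    Wc = np.ascontiguousarray(W - col_means)
    Xd = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    Xd = np.ascontiguousarray(Xd)
    out = _bl_gibbs(
        y.copy(), Wc, Xd, int(iterations), int(burn_in), int(seed) % (2 ** 31),
        fix_sigma2 is not None, float(fix_sigma2 or 1.0),
        fix_lambda2 is not None, float(fix_lambda2 or 1.0),
        float(r_prior), float(delta_prior))
    q, b, s2, l2 = out
    if not (np.all(np.isfinite(q)) and np.isfinite(s2)):
        raise RuntimeError(f"divergent Gibbs chain: sigma2={s2}, "
                           f"max|effect|={np.nanmax(np.abs(q))}")
    return BayesianLassoFit(b, q, float(s2), float(l2), col_means)


# ---------------------------------------------------------------------------
# RKHS / GBLUP (Gibbs on the eigenbasis of G)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RkhsFit:
    beta: np.ndarray
    g: np.ndarray               # posterior-mean genetic values (training lines)
    s2_g: float
    s2_e: float
    G_train: np.ndarray

    def predict_new(self, G_cross: np.ndarray, X_new: np.ndarray | None = None,
                    jitter: float = 1e-6) -> np.ndarray:
        """Genetic values for unphenotyped lines via the kernel cross-block."""
        n = self.G_train.shape[0]
        A = self.G_train + jitter * np.eye(n)
        g_new = G_cross @ np.linalg.solve(A, self.g)
        m = G_cross.shape[0]
        X = np.ones((m, 1)) if X_new is None else np.column_stack([np.ones(m), X_new])
        return X @ self.beta + g_new


def fit_rkhs_gibbs(G: np.ndarray, y: np.ndarray, X: np.ndarray | None = None,
                   iterations: int = 10_000, burn_in: int = 1_000,
                   seed: int = 0, prior_df: float = 5.0,
                   prior_r2: float = 0.5) -> RkhsFit:
    """Bayesian GBLUP with kernel G, Gibbs-sampled on the eigenbasis of G.

    Variance priors are scaled-inverse-chi-square with ``prior_df`` degrees
    of freedom, scaled so the prior partitions var(y) according to
    ``prior_r2`` (genetic) vs its complement (residual).
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    G = np.asarray(G, float)
    w, U = np.linalg.eigh((G + G.T) / 2.0)
    neg = w < -1e-8
    if neg.any():
        raise ValueError("G is not PSD; add jitter before fitting")
    w = np.maximum(w, 0.0)
    pos = w > 1e-10
    Xd = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), X])
    p = Xd.shape[1]
    yt = U.T @ y
    Xt = U.T @ Xd
    XtX = Xt.T @ Xt
    XtX_chol = np.linalg.cholesky(np.linalg.inv(XtX))

    vy = float(np.var(y))
    mean_w = max(float(np.mean(w[pos])), 1e-12)
    nu = prior_df
    # scaled-inv-chi2 scales chosen so the prior mean splits var(y) by prior_r2
    Sg = prior_r2 * vy / mean_w * (nu - 2.0) / nu
    Se = (1.0 - prior_r2) * vy * (nu - 2.0) / nu

    rng = np.random.default_rng(seed)
    a = np.zeros(n)
    b = np.zeros(p)
    s2g = max(prior_r2 * vy / mean_w, 1e-8)
    s2e = max((1 - prior_r2) * vy, 1e-8)

    a_sum = np.zeros(n)
    b_sum = np.zeros(p)
    s2g_sum = s2e_sum = 0.0
    kept = 0
    n_pos = int(pos.sum())
    for it in range(int(iterations)):
        # fixed effects (flat prior)
        r = yt - a
        mean_b = np.linalg.solve(XtX, Xt.T @ r)
        b = mean_b + np.sqrt(s2e) * (XtX_chol @ rng.standard_normal(p))
        # genetic coefficients on the eigenbasis
        r = yt - Xt @ b
        var_a = np.zeros(n)
        var_a[pos] = 1.0 / (1.0 / s2e + 1.0 / (w[pos] * s2g))
        mean_a = var_a * r / s2e
        a = np.where(pos, mean_a + np.sqrt(var_a) * rng.standard_normal(n), 0.0)
        # variances (scaled-inverse-chi-square)
        ss_g = float(np.sum(a[pos] ** 2 / w[pos]))
        s2g = (ss_g + nu * Sg) / rng.chisquare(n_pos + nu)
        e = yt - Xt @ b - a
        s2e = (float(e @ e) + nu * Se) / rng.chisquare(n + nu)
        if it >= burn_in:
            kept += 1
            a_sum += a
            b_sum += b
            s2g_sum += s2g
            s2e_sum += s2e
    a_bar = a_sum / kept
    return RkhsFit(b_sum / kept, U @ a_bar, s2g_sum / kept, s2e_sum / kept, G)


# ---------------------------------------------------------------------------
# WGBLUP
# ---------------------------------------------------------------------------


def fit_wgblup(W: np.ndarray, y_train: np.ndarray, train_idx: np.ndarray,
               geno: GenotypeMatrix | None = None,
               X: np.ndarray | None = None,
               pvalues: np.ndarray | None = None,
               pvalues_from_idx: np.ndarray | None = None,
               iterations: int = 10_000, burn_in: int = 1_000,
               seed: int = 0) -> tuple[RkhsFit, np.ndarray]:
    """Weighted GBLUP: kinship weighted by training-fold GWAS p-values.

    ``W`` covers all lines; the model is trained on ``train_idx`` with
    response ``y_train``.  P-values are computed internally on the training
    partition unless supplied, in which case ``pvalues_from_idx`` must prove
    they derive from training lines only — anything else raises
    :class:`LeakageError`.

    Returns the fitted model plus the full weighted kinship G* (all lines),
    for cross-block prediction.
    """
    train_idx = np.asarray(train_idx, int)
    if pvalues is None:
        sub = GenotypeMatrix(
            W[train_idx],
            geno.markers if geno is not None else _default_markers(W.shape[1]),
            (geno.samples.iloc[train_idx].reset_index(drop=True)
             if geno is not None else pd.DataFrame({"id": [f"s{i}" for i in train_idx]})),
        )
        scan = association_scan(sub, y_train, covariates=X)
        pvalues = np.nan_to_num(scan.table["p"].to_numpy(), nan=1.0)
    else:
        if pvalues_from_idx is None:
            raise LeakageError("supplied p-values must declare their source lines")
        extra = set(np.asarray(pvalues_from_idx, int)) - set(train_idx)
        if extra:
            raise LeakageError(
                "weight p-values were computed on lines outside the training "
                f"partition: {sorted(extra)[:5]} ...")
    d = pvalue_weights(pvalues)
    G_star = kinship_vanraden(W, weights=d)
    fit = fit_rkhs_gibbs(G_star[np.ix_(train_idx, train_idx)], y_train,
                         X=X, iterations=iterations, burn_in=burn_in, seed=seed)
    return fit, G_star


def _default_markers(m: int) -> pd.DataFrame:
    return pd.DataFrame({"id": [f"m{j}" for j in range(m)],
                         "chrom": ["Chr01"] * m,
                         "pos": np.arange(1, m + 1)})


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PredictionReport:
    replicates: pd.DataFrame    # model, repeat, fold, r, n_valid

    @property
    def mean(self) -> float:
        return float(self.replicates["r"].mean())

    @property
    def sd(self) -> float:
        return float(self.replicates["r"].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        return (self.replicates.groupby("model")["r"]
                .agg(["mean", "std", "count"]).reset_index())


def _fit_predict(model: str, W: np.ndarray, y: np.ndarray,
                 train: np.ndarray, test: np.ndarray,
                 X: np.ndarray | None, G: np.ndarray | None,
                 geno: GenotypeMatrix | None,
                 gibbs: tuple[int, int], seed: int) -> np.ndarray:
    Xtr = None if X is None else X[train]
    Xte = None if X is None else X[test]
    if model == "rrBLUP":
        fit = fit_rrblup(W[train], y[train], X=Xtr)
        return fit.predict(W[test], X_new=Xte)
    if model == "BL":
        fit = fit_bayesian_lasso(W[train], y[train], X=Xtr,
                                 iterations=gibbs[0], burn_in=gibbs[1], seed=seed)
        return fit.predict(W[test], X_new=Xte)
    if model == "RKHS":
        fit = fit_rkhs_gibbs(G[np.ix_(train, train)], y[train], X=Xtr,
                             iterations=gibbs[0], burn_in=gibbs[1], seed=seed)
        return fit.predict_new(G[np.ix_(test, train)], X_new=Xte)
    if model == "WGBLUP":
        fit, G_star = fit_wgblup(W, y[train], train, geno=geno, X=Xtr,
                                 iterations=gibbs[0], burn_in=gibbs[1], seed=seed)
        return fit.predict_new(G_star[np.ix_(test, train)], X_new=Xte)
    raise ValueError(f"unknown model {model!r}")


def cross_validate(spec: GsModelSpec, W: np.ndarray, y: np.ndarray,
                   X: np.ndarray | None = None,
                   geno: GenotypeMatrix | None = None,
                   folds: int = 10, repeats: int = 10,
                   seed: int | None = None) -> PredictionReport:
    """Repeated k-fold cross-validation; predictive ability per held-out fold."""
    W = np.asarray(W, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    seed = spec.seed if seed is None else seed
    X = X if spec.include_structure else None
    G = kinship_vanraden(W) if spec.model == "RKHS" else None
    gibbs = (spec.gibbs_iterations, spec.gibbs_burn_in)
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(n)
        fold_of = np.empty(n, int)
        fold_of[perm] = np.arange(n) % folds
        for f in range(folds):
            test = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            pred = _fit_predict(spec.model, W, y, train, test, X, G, geno,
                                gibbs, int(rng.integers(2 ** 31)))
            obs = y[test]
            if np.std(obs) == 0 or np.std(pred) == 0:
                rows.append((spec.model, rep, f, np.nan, len(test)))
                continue
            r = float(np.corrcoef(pred, obs)[0, 1])
            rows.append((spec.model, rep, f, r, len(test)))
    rep_df = pd.DataFrame(rows, columns=["model", "repeat", "fold", "r", "n_valid"])
    rep_df = rep_df.dropna(subset=["r"]).reset_index(drop=True)
    return PredictionReport(rep_df)


def cross_env_validate(spec: GsModelSpec, W: np.ndarray,
                       y_train_env: np.ndarray, y_valid_env: np.ndarray,
                       X: np.ndarray | None = None,
                       geno: GenotypeMatrix | None = None,
                       repeats: int = 10, holdout: float = 0.1,
                       seed: int | None = None) -> PredictionReport:
    """Cross-environment protocol: per repeat, hold out ``holdout`` of the
    lines, train on the training environment's BLUPs of the rest, and
    correlate predictions with the validation environment's BLUPs of the
    held-out lines (avoids same-line leakage across environments)."""
    y_a = np.asarray(y_train_env, float).ravel()
    y_b = np.asarray(y_valid_env, float).ravel()
    if y_a.size != y_b.size:
        raise ValueError("line sets not identical across environments")
    n = y_a.size
    seed = spec.seed if seed is None else seed
    X = X if spec.include_structure else None
    G = kinship_vanraden(W) if spec.model == "RKHS" else None
    gibbs = (spec.gibbs_iterations, spec.gibbs_burn_in)
    n_hold = max(int(round(holdout * n)), 2)
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(n)
        test, train = perm[:n_hold], perm[n_hold:]
        pred = _fit_predict(spec.model, W, y_a, train, test, X, G, geno,
                            gibbs, int(rng.integers(2 ** 31)))
        obs = y_b[test]
        r = (np.nan if np.std(obs) == 0 or np.std(pred) == 0
             else float(np.corrcoef(pred, obs)[0, 1]))
        rows.append((spec.model, rep, 0, r, n_hold))
    rep_df = pd.DataFrame(rows, columns=["model", "repeat", "fold", "r", "n_valid"])
    rep_df = rep_df.dropna(subset=["r"]).reset_index(drop=True)
    return PredictionReport(rep_df)
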