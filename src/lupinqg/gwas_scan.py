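"""Covariate-adjusted single-marker association scan.

Each SNP is tested in the fixed-effect linear model

    response ~ intercept + structure covariates + dosage,

with a two-sided t-test on the dosage coefficient (computed for all markers
at once via Frisch-Waugh residualization).  An optional kinship-whitened
variant pre-multiplies response, covariates and dosages by the inverse
Cholesky factor of the estimated VanRaden-kinship covariance, turning the
scan into a GLS.  Significance is controlled by a Bonferroni threshold
(default family-wise alpha 0.01 over the number of markers actually tested),
and per-SNP explained variance is the incremental R2 of the SNP over the
covariate-only model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix


@dataclasses.dataclass
class GwasResult:
    table: pd.DataFrame          # id, chrom, pos, effect, se, p, maf
    m_tested: int
    alpha: float
    threshold: float
    significant: pd.DataFrame
    lambda_gc: float
    skipped_monomorphic: int


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, float))
    if C.shape[0] != n:
        C = C.T
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariate set")
    return X


def association_scan(geno: GenotypeMatrix, response: np.ndarray,
                     covariates: np.ndarray | None = None,
                     alpha: float = 0.01,
                     kinship_whiten: bool = False) -> GwasResult:
    """Scan all markers; requires a complete (imputed) genotype matrix."""
    W = geno.dosage
    if np.isnan(W).any():
        raise ValueError("association_scan requires a complete matrix")
    y = np.asarray(response, float).ravel()
    n = y.size
    if W.shape[0] != n:
        raise ValueError("response length does not match number of lines")
    X = _design(n, covariates)

    if kinship_whiten:
        from .genomic_prediction import kinship_vanraden
        from ._reml import kernel_reml
        G = kinship_vanraden(W)
        res = kernel_reml(G, y, X)
        V = res.s2_g * G + res.s2_e * np.eye(n)
        L = np.linalg.cholesky(V)
        y = np.linalg.solve(L, y)
        X = np.linalg.solve(L, X)
        W = np.linalg.solve(L, W)

    # Frisch-Waugh: residualize response and markers on the covariate design
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    W_r = W - Q @ (Q.T @ W)
    xx = np.sum(W_r ** 2, axis=0)
    mono = xx <= 1e-12 * n
    df = n - X.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (W_r.T @ y_r) / xx
        rss = np.sum(y_r ** 2) - beta ** 2 * xx
        se = np.sqrt(np.maximum(rss, 0.0) / df / xx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[mono] = np.nan

    maf = geno.maf()
    table = pd.DataFrame({
        "id": geno.markers["id"].to_numpy(),
        "chrom": geno.markers["chrom"].to_numpy(),
        "pos": geno.markers["pos"].to_numpy(),
        "effect": beta, "se": se, "p": p, "maf": maf,
    })
    tested = table.dropna(subset=["p"])
    m = len(tested)
    threshold = alpha / m if m else np.nan
    sig = tested[tested["p"] < threshold].sort_values("p")
    chi2 = stats.chi2.isf(tested["p"].to_numpy(), 1)
    lam = float(np.median(chi2) / stats.chi2.isf(0.5, 1)) if m else np.nan
    return GwasResult(table, m, alpha, threshold, sig.reset_index(drop=True),
                      lam, int(mono.sum()))


def bonferroni_hits(pvals: np.ndarray, alpha: float = 0.01,
                    m: int | None = None) -> np.ndarray:
    """Indices of p-values below alpha/m (m defaults to len(pvals))."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.empty(0, int)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.flatnonzero(p < alpha / m)


def explained_variance(geno: GenotypeMatrix, response: np.ndarray,
                       hit_indices: np.ndarray,
                       covariates: np.ndarray | None = None) -> tuple[pd.DataFrame, float]:
    """Incremental R2 (in %) of each significant SNP over the covariate-only
    model, and the trait total as their sum."""
    hit_indices = np.asarray(hit_indices, int)
    if hit_indices.size == 0:
        return pd.DataFrame(columns=["id", "chrom", "pos", "variance_pct", "maf"]), 0.0
    y = np.asarray(response, float).ravel()
    n = y.size
    X0 = _design(n, covariates)
    Q0, _ = np.linalg.qr(X0)
    rss0 = np.sum((y - Q0 @ (Q0.T @ y)) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    r2_0 = 1.0 - rss0 / tss
    rows = []
    maf = geno.maf()
    for j in hit_indices:
        X1 = np.column_stack([X0, geno.dosage[:, j]])
        if np.linalg.matrix_rank(X1) < X1.shape[1]:
            # SNP absorbed by covariates: marginal fallback
            r = np.corrcoef(y, geno.dosage[:, j])[0, 1]
            inc = float(r * r)
        else:
            Q1, _ = np.linalg.qr(X1)
            rss1 = np.sum((y - Q1 @ (Q1.T @ y)) ** 2)
            inc = (1.0 - rss1 / tss) - r2_0
        rows.append((geno.markers["id"].iat[j], geno.markers["chrom"].iat[j],
                     geno.markers["pos"].iat[j], 100.0 * max(inc, 0.0), maf[j]))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos", "variance_pct", "maf"])
    return df, float(df["variance_pct"].sum())
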