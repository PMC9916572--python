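"""Population structure by discriminant analysis of principal components.

The pipeline mirrors standard DAPC practice: an ordinary PCA of the centered
dosage matrix (all components kept), k-means over K = 1..K_max on the PC
scores with the Bayesian information criterion

    BIC(K) = n ln(WSS_K / n) + K ln(n)

selecting K, then a linear discriminant analysis of the cluster labels on a
reduced set of PC scores.  The number of discriminant axes to retain is
chosen by the a-score: observed reassignment success minus the mean success
over label-permuted replicates, per axis count.  The retained, standardized
scores serve as structure covariates for GWAS and genomic prediction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["StructureResult", "select_k", "dpca", "structure_covariates"]


@dataclasses.dataclass
class StructureResult:
    bic_curve: pd.DataFrame            # columns K, BIC
    K_selected: int
    assignments: np.ndarray            # cluster label per line
    retained_axes: int
    scores: np.ndarray                 # lines x retained discriminant axes
    a_scores: pd.DataFrame | None = None   # columns n_axes, a_score
    reassignment_success: np.ndarray | None = None  # observed, per axis count
    sample_ids: list | None = None


def _pc_scores(dosage: np.ndarray) -> np.ndarray:
    X = dosage - dosage.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > 1e-10 * (s[0] if s.size else 1.0)
    return U[:, keep] * s[keep]


def select_k(dosage: np.ndarray, k_max: int = 20, seed: int = 0,
             n_restarts: int = 10) -> tuple[pd.DataFrame, int]:
    """BIC-over-K curve from k-means on the full PC score matrix.

    Ties and the argmin both resolve toward the smallest K.
    """
    if np.isnan(dosage).any():
        raise ValueError("select_k requires a complete (imputed) matrix")
    n = dosage.shape[0]
    if k_max >= n:
        warnings.warn(f"k_max {k_max} >= n_samples {n}; capped at {n - 1}")
        k_max = n - 1
    scores = _pc_scores(dosage)
    rows = []
    total_ss = float(np.sum((scores - scores.mean(axis=0)) ** 2))
    for K in range(1, k_max + 1):
        if K == 1:
            wss = total_ss
        else:
            km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
            km.fit(scores)
            wss = float(km.inertia_)
        bic = n * np.log(max(wss, 1e-300) / n) + K * np.log(n)
        rows.append((K, bic))
    curve = pd.DataFrame(rows, columns=["K", "BIC"])
    K_selected = int(curve.loc[curve["BIC"].idxmin(), "K"])
    return curve, K_selected


def dpca(dosage: np.ndarray, K_selected: int, seed: int = 0,
         n_pca: int | None = None, n_permutations: int = 20,
         labels: np.ndarray | None = None,
         sample_ids=None) -> StructureResult:
    """Discriminant analysis of cluster labels on PC scores with a-score
    axis retention.

    ``n_pca`` limits the PC scores fed to the LDA (default min(n//3, 50,
    n-K-1), the usual rule keeping the discriminant problem well-posed).
    ``labels`` overrides the internal k-means clustering (e.g. for
    permutation-null diagnostics).
    """
    if np.isnan(dosage).any():
        raise ValueError("dpca requires a complete (imputed) matrix")
    n = dosage.shape[0]
    scores_pc = _pc_scores(dosage)
    if n_pca is None:
        n_pca = min(n // 3, 50, max(n - K_selected - 1, 1))
    pcs = scores_pc[:, :max(n_pca, 1)]

    rng = np.random.default_rng(seed)
    if K_selected == 1:
        return StructureResult(pd.DataFrame(columns=["K", "BIC"]), 1,
                               np.zeros(n, int), 0, np.empty((n, 0)),
                               sample_ids=sample_ids)

    if labels is None:
        km = KMeans(n_clusters=K_selected, n_init=10, random_state=seed)
        labels = km.fit_predict(pcs)
    else:
        labels = np.asarray(labels)
    observed = _lda_success(pcs, labels)
    permuted = np.zeros(len(observed))
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        s = _lda_success(pcs, perm)
        # permuted label sets can yield fewer discriminant axes; pad
        permuted[:len(s)] += np.pad(s, (0, len(observed) - len(s)),
                                    constant_values=s[-1] if len(s) else 0.0)[:len(observed)]
    permuted /= n_permutations
    a = observed - permuted
    retained = int(np.argmax(a)) + 1
    lda = LinearDiscriminantAnalysis()
    lda.fit(pcs, labels)
    full_scores = lda.transform(pcs)
    a_df = pd.DataFrame({"n_axes": np.arange(1, len(a) + 1), "a_score": a})
    return StructureResult(pd.DataFrame(columns=["K", "BIC"]), K_selected,
                           labels, retained, full_scores[:, :retained],
                           a_scores=a_df, reassignment_success=observed,
                           sample_ids=sample_ids)


def _lda_success(pcs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Reassignment success (nearest class centroid in discriminant space)
    for each axis count 1..n_axes."""
    classes = np.unique(labels)
    if classes.size < 2:
        return np.array([1.0])
    lda = LinearDiscriminantAnalysis()
    lda.fit(pcs, labels)
    Z = lda.transform(pcs)
    n_axes = Z.shape[1]
    out = np.empty(n_axes)
    for r in range(1, n_axes + 1):
        Zr = Z[:, :r]
        cents = np.stack([Zr[labels == c].mean(axis=0) for c in classes])
        d2 = ((Zr[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        pred = classes[np.argmin(d2, axis=1)]
        out[r - 1] = float(np.mean(pred == labels))
    return out


def structure_covariates(result: StructureResult, n_axes: int = 7) -> np.ndarray:
    """Column-standardized discriminant scores (lines x min(n_axes, retained));
    n_axes = 0 gives an empty matrix for structure-free analyses."""
    if n_axes == 0 or result.retained_axes == 0:
        return np.empty((result.scores.shape[0], 0))
    k = min(n_axes, result.retained_axes)
    Z = result.scores[:, :k]
    sd = Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (Z - Z.mean(axis=0)) / sd
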