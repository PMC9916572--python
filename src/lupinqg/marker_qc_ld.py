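"""Genotype-matrix quality control, imputation, and LD-decay estimation.

Filtering follows a fixed order: monomorphic markers, MAF, per-marker
missingness, per-sample missingness, then MAF is recomputed once and
re-filtered (sample removal can shift allele frequencies).  Heterozygosity
excess is screened separately: samples above mean + 3 SD and markers above
mean + 2 SD of their respective heterozygosity-rate distributions are
removed, with the thresholds computed before any removal and samples
filtered first.

Imputation offers three seeded, categorical-output methods: per-marker mode,
k-nearest-neighbour on dosages, and an "rf-like" scheme that trains a bagged
classification forest per marker on its most-correlated neighbouring markers.

LD decay is the squared Pearson correlation (r2) between all marker pairs
within a window (default 50 kb) per chromosome, summarized by a degree-2
polynomial fit and the smallest distance at which the fitted curve drops to
half of the 90th percentile of pairwise r2.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

MISSING_RATE_PRESETS = (0.15, 0.20, 0.30)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_markers_samples(geno: GenotypeMatrix, maf_min: float = 0.05,
                           miss_marker_max: float = 0.30,
                           miss_sample_max: float = 0.50) -> GenotypeMatrix:
    """Apply the standard QC cascade; raises if nothing survives a step."""
    if not 0.0 < miss_marker_max <= 1.0:
        raise ValueError("miss_marker_max must be in (0, 1]")
    g = geno

    def _check(mask, what, axis):
        if not mask.any():
            raise ValueError(f"no {axis} left after the {what} threshold")

    maf = g.maf()
    keep = maf > 0                                   # monomorphic
    _check(keep, "monomorphic-marker", "markers")
    g = g.subset(marker_mask=keep)

    keep = g.maf() >= maf_min
    _check(keep, f"MAF >= {maf_min}", "markers")
    g = g.subset(marker_mask=keep)

    keep = g.marker_missing_rate() <= miss_marker_max
    _check(keep, f"marker missingness <= {miss_marker_max}", "markers")
    g = g.subset(marker_mask=keep)

    keep_s = g.sample_missing_rate() <= miss_sample_max
    _check(keep_s, f"sample missingness <= {miss_sample_max}", "samples")
    g = g.subset(sample_mask=keep_s)

    # one recomputation pass: sample removal can change MAF
    keep = (g.maf() >= maf_min) & (g.maf() > 0)
    _check(keep, "post-sample-removal MAF", "markers")
    return g.subset(marker_mask=keep)


def filter_het_excess(geno: GenotypeMatrix, sample_sd: float = 3.0,
                      marker_sd: float = 2.0) -> GenotypeMatrix:
    """Remove heterozygosity-excess outliers (samples first, thresholds from
    the pre-removal distributions); zero-SD distributions remove nothing."""
    s_het = geno.sample_het_rate()
    m_het = geno.marker_het_rate()
    s_mu, s_sd = np.nanmean(s_het), np.nanstd(s_het)
    m_mu, m_sd = np.nanmean(m_het), np.nanstd(m_het)
    keep_s = np.ones(geno.n_lines, bool) if s_sd == 0 else ~(s_het > s_mu + sample_sd * s_sd)
    keep_m = np.ones(geno.n_markers, bool) if m_sd == 0 else ~(m_het > m_mu + marker_sd * m_sd)
    return geno.subset(sample_mask=keep_s, marker_mask=keep_m)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _mode_fill(dosage: np.ndarray) -> np.ndarray:
    out = dosage.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"marker column {j} is entirely missing; pre-filter it")
        counts = np.bincount(obs.astype(int), minlength=3)
        out[miss, j] = float(np.argmax(counts))
    return out


def impute_missing(geno: GenotypeMatrix, method: str = "rf-like",
                   seed: int = 0, knn_k: int = 5, rf_trees: int = 100,
                   rf_neighbors: int = 10) -> GenotypeMatrix:
    """Return a complete categorical ({0,1,2}) genotype matrix.

    Methods: ``mode`` (per-marker majority call), ``knn`` (nearest samples by
    dosage distance, majority vote), ``rf-like`` (per-marker bagged
    classification trees on the most-correlated markers — a stand-in in the
    MissForest spirit).  Observed calls are never altered.
    """
    dosage = geno.dosage
    miss_mask = np.isnan(dosage)
    if not miss_mask.any():
        return geno.copy()
    if np.any(miss_mask.all(axis=0)):
        raise ValueError("all-missing marker present; pre-filter it")

    if method == "mode":
        filled = _mode_fill(dosage)
    elif method == "knn":
        filled = _knn_impute(dosage, knn_k)
    elif method == "rf-like":
        filled = _rf_impute(dosage, seed, rf_trees, rf_neighbors)
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    filled[~miss_mask] = dosage[~miss_mask]
    out = geno.copy()
    out.dosage = filled
    return out


def _knn_impute(dosage: np.ndarray, k: int) -> np.ndarray:
    """Majority vote over the k nearest samples (mean-squared dosage distance
    on shared non-missing markers)."""
    n = dosage.shape[0]
    filled = _mode_fill(dosage)
    out = dosage.copy()
    # pairwise distances on the mode-filled matrix (stable, fast)
    sq = np.sum(filled ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * filled @ filled.T
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1)
    for i in range(n):
        miss_j = np.flatnonzero(np.isnan(dosage[i]))
        if miss_j.size == 0:
            continue
        for j in miss_j:
            votes = []
            for nb in order[i]:
                if not np.isnan(dosage[nb, j]):
                    votes.append(int(dosage[nb, j]))
                    if len(votes) == k:
                        break
            if votes:
                out[i, j] = float(np.argmax(np.bincount(votes, minlength=3)))
            else:
                out[i, j] = filled[i, j]
    return out


def _rf_impute(dosage: np.ndarray, seed: int, n_trees: int, n_neighbors: int) -> np.ndarray:
    from sklearn.ensemble import RandomForestClassifier

    filled = _mode_fill(dosage)
    out = dosage.copy()
    sd = filled.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(filled)
    Z[:, ok] = (filled[:, ok] - filled[:, ok].mean(axis=0)) / sd[ok]
    C = np.abs(Z.T @ Z) / Z.shape[0]
    np.fill_diagonal(C, -1.0)
    rng = np.random.default_rng(seed)
    for j in range(dosage.shape[1]):
        miss = np.isnan(dosage[:, j])
        if not miss.any():
            continue
        nb = np.argsort(C[j])[::-1][:n_neighbors]
        Xtr, ytr = filled[~miss][:, nb], dosage[~miss, j].astype(int)
        if np.unique(ytr).size == 1:
            out[miss, j] = float(ytr[0])
            continue
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)),
            n_jobs=1)
        clf.fit(Xtr, ytr)
        out[miss, j] = clf.predict(filled[miss][:, nb]).astype(float)
    return out


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LdDecayCurve:
    per_chromosome: dict            # chrom -> DataFrame(dist_bp, r2)
    poly_coefs: dict                # chrom -> ndarray (degree-2 fit)
    half_decay_bp: dict             # chrom -> float or NaN
    r2_q90: float                   # 90th percentile of all pairwise r2
    half_decay_mean_bp: float

    def pairs(self) -> pd.DataFrame:
        frames = []
        for ch, df in self.per_chromosome.items():
            d = df.copy()
            d.insert(0, "chrom", ch)
            frames.append(d)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "dist_bp", "r2"])


def ld_decay(geno: GenotypeMatrix, window: int = 50_000) -> LdDecayCurve:
    """Pairwise r2 vs physical distance within ``window`` per chromosome.

    Requires a complete (imputed) matrix.  Each chromosome gets a degree-2
    polynomial fit, made monotone non-increasing over the data range by a
    running-minimum clip; the half-decay summary is the smallest distance
    where the clipped fit drops to half of the 90th percentile of all
    pairwise r2 on that chromosome.
    """
    if np.isnan(geno.dosage).any():
        raise ValueError("ld_decay requires a complete (imputed) matrix")
    per, coefs, halves = {}, {}, {}
    all_r2 = []
    for chrom, grp in geno.markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            warnings.warn(f"{chrom}: fewer than 2 markers, skipped")
            continue
        pos = grp["pos"].to_numpy()
        X = geno.dosage[:, idx]
        sd = X.std(axis=0)
        dists, r2s = [], []
        for a in range(idx.size - 1):
            if sd[a] == 0:
                continue
            hi = np.searchsorted(pos, pos[a] + window, side="right")
            for b in range(a + 1, hi):
                if sd[b] == 0:
                    continue
                r = np.corrcoef(X[:, a], X[:, b])[0, 1]
                dists.append(pos[b] - pos[a])
                r2s.append(r * r)
        if not dists:
            warnings.warn(f"{chrom}: no marker pairs within {window} bp, skipped")
            continue
        df = pd.DataFrame({"dist_bp": dists, "r2": r2s})
        per[chrom] = df
        all_r2.append(df["r2"].to_numpy())
        if df["dist_bp"].nunique() >= 3:
            coefs[chrom] = np.polyfit(df["dist_bp"], df["r2"], 2)
        else:
            coefs[chrom] = np.array([0.0, 0.0, float(df["r2"].mean())])
        halves[chrom] = _half_decay(df, coefs[chrom])
    r2_all = np.concatenate(all_r2) if all_r2 else np.array([np.nan])
    finite = [v for v in halves.values() if np.isfinite(v)]
    return LdDecayCurve(per, coefs, halves,
                        float(np.percentile(r2_all, 90)) if all_r2 else np.nan,
                        float(np.mean(finite)) if finite else np.nan)


def _half_decay(df: pd.DataFrame, coef: np.ndarray) -> float:
    target = 0.5 * np.percentile(df["r2"], 90)
    lo, hi = df["dist_bp"].min(), df["dist_bp"].max()
    grid = np.linspace(lo, hi, 512)
    fit = np.minimum.accumulate(np.clip(np.polyval(coef, grid), 0.0, 1.0))
    below = np.flatnonzero(fit <= target)
    return float(grid[below[0]]) if below.size else np.nan
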