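"""Multi-environment trial statistics: variance components, heritability,
BLUPs, genotype x environment interaction, and genetic correlation.

Per environment, the model is y_ib = mu + g_i + b_b + e_ib with genotype and
block random for component estimation (REML) and genotype fixed for the
F-test.  Broad-sense heritability is on a line-mean basis,

    H2 = s2_g / (s2_g + s2_e / n),

with n the number of blocks, and the genetic coefficient of variation is
CV = 100 * s_g / m.  The combined model adds a genotype-x-environment random
term with environment fixed.  The default cross-environment genetic
correlation estimator is the heritability-corrected phenotypic correlation of
line means (Burdon-type),

    r_g = corr(mean_1, mean_2) / sqrt(H2_1 * H2_2),

with a nonparametric bootstrap SE over lines; the homogeneous-variance
estimator s2_G / (s2_G + s2_GEI) is available as an alternative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_variance_components
from .containers import ENVIRONMENTS

__all__ = [
    "VarianceDecomposition",
    "fit_single_env",
    "blup_line_values",
    "fit_combined",
    "test_rg_vs_unity",
    "trait_correlations",
    "anova_moment_components",
]


@dataclasses.dataclass
class VarianceDecomposition:
    s2_g: float
    s2_e: float
    s2_block: float = np.nan
    s2_gei: float = np.nan
    n_reps: int = 0
    mean: float = np.nan
    cv_pct: float = np.nan
    H2: float = np.nan
    H2_se: float = np.nan
    rg: float = np.nan
    rg_se: float = np.nan
    geno_F: float = np.nan
    geno_p: float = np.nan
    env_F: float = np.nan
    env_p: float = np.nan
    flags: tuple = ()


def _pivot(plots: pd.DataFrame, trait: str, environment: str) -> pd.DataFrame:
    sub = plots[plots["environment"] == environment]
    if sub.empty:
        raise ValueError(f"no records for environment {environment!r}")
    wide = sub.pivot_table(index="line_id", columns="block", values=trait)
    if wide.isna().any().any():
        raise ValueError("unbalanced layout: missing line x block cells")
    return wide


def anova_moment_components(wide: pd.DataFrame) -> dict:
    """Balanced two-way ANOVA (lines x blocks, one obs/cell) moment estimators.

    Returns mean squares and the method-of-moments genotypic variance
    (MS_G - MS_E) / n_blocks, which equals the REML solution on balanced data
    whenever it is non-negative.
    """
    Y = wide.to_numpy(float)
    g, b = Y.shape
    gm = Y.mean()
    line_m = Y.mean(axis=1)
    block_m = Y.mean(axis=0)
    ss_g = b * np.sum((line_m - gm) ** 2)
    ss_b = g * np.sum((block_m - gm) ** 2)
    ss_t = np.sum((Y - gm) ** 2)
    ss_e = ss_t - ss_g - ss_b
    df_g, df_b = g - 1, b - 1
    df_e = df_g * df_b
    ms_g = ss_g / df_g
    ms_b = ss_b / df_b
    ms_e = ss_e / df_e if df_e > 0 else np.nan
    return {
        "MS_G": ms_g, "MS_B": ms_b, "MS_E": ms_e,
        "df_G": df_g, "df_B": df_b, "df_E": df_e,
        "s2_g_mom": (ms_g - ms_e) / b,
        "s2_b_mom": (ms_b - ms_e) / g,
        "F_G": ms_g / ms_e if ms_e > 0 else np.inf,
    }


def fit_single_env(plots: pd.DataFrame, trait: str, environment: str
                   ) -> VarianceDecomposition:
    """REML variance components, CV, and line-mean heritability for one
    environment; the genotype significance test treats genotype as fixed."""
    wide = _pivot(plots, trait, environment)
    g, b = wide.shape
    if b < 2:
        raise ValueError("at least 2 blocks required (singular design)")
    if g < 2:
        raise ValueError("at least 2 lines required")
    y = wide.to_numpy(float).ravel()
    mean = float(y.mean())
    flags: list[str] = []

    if np.var(y) == 0.0:
        return VarianceDecomposition(0.0, 0.0, 0.0, n_reps=b, mean=mean,
                                     cv_pct=0.0, H2=0.0,
                                     flags=("zero_variance", "H2_undefined"))

    Zg = np.kron(np.eye(g), np.ones((b, 1)))
    Zb = np.kron(np.ones((g, 1)), np.eye(b))
    res = reml_variance_components(y, np.ones((y.size, 1)), [Zg, Zb])
    s2_g, s2_b, s2_e = res.variances
    if res.clamped[0]:
        flags.append("s2_g_clamped_zero")

    an = anova_moment_components(wide)
    p_geno = float(stats.f.sf(an["F_G"], an["df_G"], an["df_E"]))

    cv = 100.0 * np.sqrt(s2_g) / mean if mean != 0 else np.nan
    denom = s2_g + s2_e / b
    if denom > 0 and s2_g > 0:
        H2 = s2_g / denom
        # delta-method SE from the balanced-ANOVA identity H2 = 1 - MSE/MSG
        H2_se = (1 - H2) * np.sqrt(2.0 / an["df_G"] + 2.0 / an["df_E"])
    else:
        H2, H2_se = 0.0, np.nan
        flags.append("H2_undefined")
    return VarianceDecomposition(
        float(s2_g), float(s2_e), float(s2_b), n_reps=b, mean=mean,
        cv_pct=float(cv), H2=float(H2), H2_se=float(H2_se),
        geno_F=float(an["F_G"]), geno_p=p_geno, flags=tuple(flags))


def blup_line_values(plots: pd.DataFrame, trait: str, environment: str,
                     decomp: VarianceDecomposition | None = None) -> pd.Series:
    """Heritability-shrunken line means: BLUP_i = m + H2 (mean_i - m).

    These shrunken values are the response variable for genomic prediction.
    """
    if decomp is None:
        decomp = fit_single_env(plots, trait, environment)
    wide = _pivot(plots, trait, environment)
    lm = wide.mean(axis=1)
    gm = lm.mean()
    out = gm + decomp.H2 * (lm - gm)
    out.name = f"{trait}_blup"
    if "H2_undefined" in decomp.flags:
        out.attrs["H2_undefined"] = True
    return out


def fit_combined(plots: pd.DataFrame, trait: str,
                 rg_estimator: str = "burdon",
                 n_boot: int = 1000, seed: int = 0) -> VarianceDecomposition:
    """Combined two-environment model: genotype, GEI and block-within-
    environment random, environment fixed; plus the genetic correlation.

    ``rg_estimator``: 'burdon' (heritability-corrected phenotypic correlation
    of line means, bootstrap SE) or 'homogeneous' (s2_G / (s2_G + s2_GEI)).
    """
    envs = [e for e in ENVIRONMENTS if (plots["environment"] == e).any()]
    if len(envs) < 2:
        raise ValueError("both environments required for the combined analysis")
    wides = {e: _pivot(plots, trait, e) for e in envs}
    lines = wides[envs[0]].index
    if not wides[envs[1]].index.equals(lines):
        raise ValueError("environments do not share the same line set")
    g = len(lines)
    b = wides[envs[0]].shape[1]

    y = np.concatenate([wides[e].to_numpy(float).ravel() for e in envs])
    n_env = len(envs)
    N = y.size
    # fixed effects: intercept + environment indicator
    env_ind = np.repeat(np.arange(n_env, dtype=float), g * b)
    X = np.column_stack([np.ones(N), env_ind])
    Zg = np.tile(np.kron(np.eye(g), np.ones((b, 1))), (n_env, 1))
    # genotype-x-environment: block diagonal over environments
    Zge = np.zeros((N, g * n_env))
    Zbe = np.zeros((N, b * n_env))
    for i in range(n_env):
        rows = slice(i * g * b, (i + 1) * g * b)
        Zge[rows, i * g:(i + 1) * g] = np.kron(np.eye(g), np.ones((b, 1)))
        Zbe[rows, i * b:(i + 1) * b] = np.kron(np.ones((g, 1)), np.eye(b))
    res = reml_variance_components(y, X, [Zg, Zge, Zbe])
    s2_G, s2_GEI, s2_B, s2_e = res.variances
    flags = []
    if res.clamped[1]:
        flags.append("s2_gei_clamped_zero")

    # environment F-test against block-within-environment
    env_means = [wides[e].to_numpy().mean() for e in envs]
    gm = float(np.mean(env_means))
    ms_env = g * b * sum((m - gm) ** 2 for m in env_means) / (n_env - 1)
    block_means = np.concatenate([wides[e].to_numpy(float).mean(axis=0) for e in envs])
    ms_block = g * np.sum((block_means - np.repeat(env_means, b)) ** 2) / (n_env * (b - 1))
    env_F = ms_env / ms_block if ms_block > 0 else np.inf
    env_p = float(stats.f.sf(env_F, n_env - 1, n_env * (b - 1)))

    # genetic correlation
    m1 = wides[envs[0]].mean(axis=1).to_numpy()
    m2 = wides[envs[1]].mean(axis=1).to_numpy()
    if rg_estimator == "homogeneous":
        tot = s2_G + s2_GEI
        rg = s2_G / tot if tot > 0 else np.nan
        rg_se = _rg_boot_se(wides, envs, "homogeneous", n_boot, seed)
    elif rg_estimator == "burdon":
        d1 = fit_single_env(plots, trait, envs[0])
        d2 = fit_single_env(plots, trait, envs[1])
        rg = _burdon_rg(m1, m2, d1.H2, d2.H2)
        if rg > 1.0 or rg < -1.0:
            flags.append("rg_truncated")
            rg = float(np.clip(rg, -1.0, 1.0))
        rg_se = _rg_boot_se(wides, envs, "burdon", n_boot, seed)
    else:
        raise ValueError(f"unknown rg estimator {rg_estimator!r}")

    mean = float(y.mean())
    return VarianceDecomposition(
        float(s2_G), float(s2_e), float(s2_B), s2_gei=float(s2_GEI),
        n_reps=b, mean=mean,
        cv_pct=100.0 * np.sqrt(s2_G) / mean if mean != 0 else np.nan,
        rg=float(rg), rg_se=float(rg_se),
        env_F=float(env_F), env_p=env_p, flags=tuple(flags))


def _burdon_rg(m1, m2, H2_1, H2_2) -> float:
    if H2_1 <= 0 or H2_2 <= 0:
        return np.nan
    r_p = np.corrcoef(m1, m2)[0, 1]
    return float(r_p / np.sqrt(H2_1 * H2_2))


def combined_moment_components(Y1: np.ndarray, Y2: np.ndarray) -> dict:
    """Balanced combined-ANOVA moment estimators for two environments.

    Expected mean squares (genotype and GEI random, blocks within
    environment): E[MS_G] = s2_e + b s2_GEI + 2b s2_G, E[MS_GE] = s2_e +
    b s2_GEI, E[MS_E] = s2_e.
    """
    g, b = Y1.shape
    Y = np.stack([Y1, Y2])                          # env x line x block
    line_m = Y.mean(axis=(0, 2))
    ge_m = Y.mean(axis=2)                           # env x line
    env_m = Y.mean(axis=(1, 2))
    gm = Y.mean()
    ss_g = 2 * b * np.sum((line_m - gm) ** 2)
    ss_ge = b * np.sum((ge_m - line_m[None, :] - env_m[:, None] + gm) ** 2)
    block_m = Y.mean(axis=1)                        # env x block
    ss_e = np.sum((Y - ge_m[:, :, None] - block_m[:, None, :] + env_m[:, None, None]) ** 2)
    df_g = g - 1
    df_ge = g - 1
    df_e = 2 * (g - 1) * (b - 1)
    ms_g, ms_ge, ms_e = ss_g / df_g, ss_ge / df_ge, ss_e / df_e
    return {
        "MS_G": ms_g, "MS_GE": ms_ge, "MS_E": ms_e,
        "s2_G_mom": (ms_g - ms_ge) / (2 * b),
        "s2_GEI_mom": (ms_ge - ms_e) / b,
        "s2_e_mom": ms_e,
    }


def _rg_boot_se(wides, envs, estimator: str, n_boot: int, seed: int) -> float:
    """Bootstrap over lines; components inside the bootstrap use the fast
    balanced moment estimators (equal to REML when non-negative)."""
    rng = np.random.default_rng(seed)
    Y1 = wides[envs[0]].to_numpy(float)
    Y2 = wides[envs[1]].to_numpy(float)
    g, b = Y1.shape
    vals = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, g, g)
        A, B = Y1[idx], Y2[idx]
        if estimator == "burdon":
            h2s = []
            for Ym in (A, B):
                an = anova_moment_components(pd.DataFrame(Ym))
                s2g = max(an["s2_g_mom"], 0.0)
                den = s2g + max(an["MS_E"], 0.0) / b
                h2s.append(s2g / den if den > 0 else 0.0)
            m1, m2 = A.mean(axis=1), B.mean(axis=1)
            if h2s[0] <= 0 or h2s[1] <= 0 or m1.std() == 0 or m2.std() == 0:
                vals[k] = np.nan
                continue
            vals[k] = np.corrcoef(m1, m2)[0, 1] / np.sqrt(h2s[0] * h2s[1])
        else:
            mom = combined_moment_components(A, B)
            s2G = max(mom["s2_G_mom"], 0.0)
            s2GEI = max(mom["s2_GEI_mom"], 0.0)
            tot = s2G + s2GEI
            vals[k] = s2G / tot if tot > 0 else np.nan
    vals = vals[np.isfinite(vals)]
    return float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan


def test_rg_vs_unity(rg: float, se: float, df: int, alpha: float = 0.05) -> dict:
    """Confidence-interval test of r_g against 1 (consistency across
    environments): reject iff rg + t_{df,1-alpha/2} * se < 1."""
    if not np.isfinite(se) or se <= 0:
        raise ValueError("SE must be positive")
    t = stats.t.ppf(1 - alpha / 2, df)
    lo, hi = rg - t * se, rg + t * se
    flag = "rg_above_unity" if rg > 1 else ""
    reject = bool(hi < 1.0) and rg <= 1.0
    return {"rg": rg, "ci": (float(lo), float(hi)), "reject_consistency": reject,
            "t_crit": float(t), "flag": flag}


def trait_correlations(line_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations (with two-sided p) among line-mean trait columns."""
    if len(line_means) < 3:
        raise ValueError("at least 3 lines required")
    cols = line_means.columns
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = line_means.iloc[:, i], line_means.iloc[:, j]
            if x.std() == 0 or y.std() == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
    return r, p
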