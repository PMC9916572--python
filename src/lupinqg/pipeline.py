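"""End-to-end analysis steps over the library modules.

Each function performs one stage of the study's analysis chain on in-memory
objects and returns plain tables/dicts; the numbered drivers under
``analysis/`` and the acceptance script are thin wrappers around these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (containers, escape_drought, genomic_prediction, gwas_scan,
               marker_qc_ld, phenotype_met, structure_dpca, synthetic_data)

FOCUS_TRAITS = ("grain_yield", "straw_biomass", "flowering_onset")


def simulate(seed: int, markers_per_chromosome: int = 400,
             **overrides):
    """Generate the factorial-cross population and its phenotypes."""
    cfg = synthetic_data.SimulationConfig(
        seed=seed, markers_per_chromosome=markers_per_chromosome, **overrides)
    geno, truth = synthetic_data.simulate_population(cfg)
    plots = synthetic_data.simulate_phenotypes(geno, truth, cfg)
    return cfg, geno, truth, plots


def met_statistics(plots: pd.DataFrame, n_boot: int = 500, seed: int = 0,
                   traits=FOCUS_TRAITS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-environment variance components table and the combined-analysis
    table (genetic correlations tested against unity)."""
    rows1, rows2 = [], []
    for trait in traits:
        for env in containers.ENVIRONMENTS:
            d = phenotype_met.fit_single_env(plots, trait, env)
            rows1.append((trait, env, d.mean, d.cv_pct, d.H2, d.H2_se,
                          d.s2_g, d.s2_e, d.geno_p))
        c = phenotype_met.fit_combined(plots, trait, n_boot=n_boot, seed=seed)
        test = phenotype_met.test_rg_vs_unity(c.rg, c.rg_se, plots["line_id"].nunique() - 1) \
            if np.isfinite(c.rg_se) and c.rg_se > 0 else {"reject_consistency": False}
        rows2.append((trait, c.s2_g, c.s2_gei, c.rg, c.rg_se,
                      bool(test["reject_consistency"]), c.env_p))
    t1 = pd.DataFrame(rows1, columns=["trait", "environment", "mean", "cv_pct",
                                      "H2", "H2_se", "s2_g", "s2_e", "geno_p"])
    t2 = pd.DataFrame(rows2, columns=["trait", "s2_G", "s2_GEI", "rg", "rg_se",
                                      "rg_below_unity", "env_p"])
    return t1, t2


def escape_analysis(plots: pd.DataFrame,
                    irrigation=escape_drought.IRRIGATION_CROP_CYCLE):
    """Escape regression, adjusted yield + its heritability, and DSI."""
    flowering = containers.line_means(plots, "flowering_onset")
    y_stress = containers.line_means(plots, "grain_yield", "stress")
    y_fav = containers.line_means(plots, "grain_yield", "favourable")
    escape = escape_drought.fit_escape_regression(flowering, y_stress)
    adj_plots, adj_decomp = escape_drought.adjusted_yield(plots, escape)
    D_S = escape_drought.drought_severity(irrigation["favourable"],
                                          irrigation["stress"])
    dsi_vals, dsi_summary = escape_drought.dsi(y_stress, y_fav, D_S)
    lines = pd.DataFrame({
        "flowering": flowering, "stress_yield": y_stress,
        "favourable_yield": y_fav,
        "adjusted_yield": escape.line_adjusted.reindex(flowering.index),
        "dsi": dsi_vals.reindex(flowering.index),
    })
    return {"escape": escape, "adjusted_plots": adj_plots,
            "adjusted_H2": adj_decomp, "D_S": D_S,
            "dsi_summary": dsi_summary, "lines": lines}


def qc_impute(geno, maf_min=0.05, miss_marker_max=0.30, miss_sample_max=0.50,
              impute="knn", seed: int = 0):
    """QC cascade + heterozygosity-excess screen + imputation."""
    g = marker_qc_ld.filter_markers_samples(
        geno, maf_min=maf_min, miss_marker_max=miss_marker_max,
        miss_sample_max=miss_sample_max)
    g = marker_qc_ld.filter_het_excess(g)
    return marker_qc_ld.impute_missing(g, method=impute, seed=seed)


def structure(geno_complete, k_max: int = 20, seed: int = 0, n_axes: int = 7):
    """K selection, DPCA, and standardized structure covariates."""
    curve, K = structure_dpca.select_k(geno_complete.dosage, k_max=k_max, seed=seed)
    res = structure_dpca.dpca(geno_complete.dosage, K, seed=seed,
                              sample_ids=list(geno_complete.samples["id"]))
    res.bic_curve = curve
    cov = structure_dpca.structure_covariates(res, n_axes=n_axes)
    return res, cov


def gwas_responses(plots: pd.DataFrame, escape_out: dict,
                   line_ids) -> dict[str, np.ndarray]:
    """The four scan responses: yield BLUPs per environment, mean flowering,
    and adjusted line yield — aligned with the genotyped line order."""
    out = {}
    for env in containers.ENVIRONMENTS:
        blup = phenotype_met.blup_line_values(plots, "grain_yield", env)
        out[f"grain_yield_{env}"] = blup.reindex(line_ids).to_numpy()
    out["flowering_onset"] = containers.line_means(
        plots, "flowering_onset").reindex(line_ids).to_numpy()
    out["adjusted_yield"] = (escape_out["lines"]["adjusted_yield"]
                             .reindex(line_ids).to_numpy())
    return out


def gwas(geno_complete, responses: dict, covariates, alpha: float = 0.01):
    """Bonferroni-controlled scans with per-hit explained variance."""
    results = {}
    for name, y in responses.items():
        scan = gwas_scan.association_scan(geno_complete, y,
                                          covariates=covariates, alpha=alpha)
        hit_idx = np.flatnonzero(scan.table["p"].to_numpy() < scan.threshold)
        ev, total = gwas_scan.explained_variance(geno_complete, y, hit_idx,
                                                 covariates=covariates)
        results[name] = {"scan": scan, "hits": ev, "total_variance_pct": total}
    return results


def prediction_grid(geno_complete, responses: dict,
                    covariates, models=genomic_prediction.MODELS,
                    traits=None, folds: int = 10, repeats: int = 2,
                    gibbs=(2000, 200), seed: int = 0,
                    structure_flags=(False, True)) -> pd.DataFrame:
    """Single-environment CV grid of models x traits."""
    W = geno_complete.dosage
    rows = []
    traits = list(responses) if traits is None else traits
    for trait in traits:
        y = responses[trait]
        for model in models:
            for structure_flag in structure_flags:
                spec = genomic_prediction.GsModelSpec(
                    model=model, include_structure=structure_flag,
                    gibbs_iterations=gibbs[0], gibbs_burn_in=gibbs[1], seed=seed)
                rep = genomic_prediction.cross_validate(
                    spec, W, y, X=covariates, geno=geno_complete,
                    folds=folds, repeats=repeats)
                rows.append((trait, model, structure_flag, rep.mean, rep.sd))
    return pd.DataFrame(rows, columns=["trait", "model", "structure",
                                       "ability_mean", "ability_sd"])


def cross_env_prediction(geno_complete, responses: dict, covariates,
                         model: str = "RKHS", repeats: int = 10,
                         gibbs=(2000, 200), seed: int = 0) -> pd.DataFrame:
    """Both directions of the cross-environment protocol for grain yield."""
    W = geno_complete.dosage
    rows = []
    pairs = [("grain_yield_stress", "grain_yield_favourable"),
             ("grain_yield_favourable", "grain_yield_stress")]
    for train_t, valid_t in pairs:
        spec = genomic_prediction.GsModelSpec(
            model=model, gibbs_iterations=gibbs[0], gibbs_burn_in=gibbs[1],
            seed=seed)
        rep = genomic_prediction.cross_env_validate(
            spec, W, responses[train_t], responses[valid_t], X=covariates,
            geno=geno_complete, repeats=repeats)
        rows.append((train_t, valid_t, model, rep.mean, rep.sd))
    return pd.DataFrame(rows, columns=["train", "validate", "model",
                                       "ability_mean", "ability_sd"])
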