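"""Association-scan calibration, power on planted QTL, Bonferroni control and
explained-variance accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lupinqg import gwas_scan as gw, pipeline, structure_dpca as st


@pytest.fixture(scope="module")
def scan_setup(sim, complete):
    res = st.dpca(complete.dosage, 16, seed=0)
    cov = st.structure_covariates(res, 7)
    from lupinqg import containers, phenotype_met
    blup = phenotype_met.blup_line_values(sim["plots"], "grain_yield", "stress")
    y = blup.reindex(complete.samples["id"]).to_numpy()
    return {"geno": complete, "cov": cov, "y": y}


def test_permutation_null_is_calibrated(scan_setup):
    """Permuted responses give uniform p-values, inflation near 1, and no
    Bonferroni hits in nearly all permutations."""
    rng = np.random.default_rng(0)
    geno, cov = scan_setup["geno"], scan_setup["cov"]
    y = scan_setup["y"]
    n_perm, with_hits, lams, ks_ps = 10, 0, [], []
    for _ in range(n_perm):
        yp = y[rng.permutation(y.size)]
        res = gw.association_scan(geno, yp, covariates=cov, alpha=0.01)
        with_hits += len(res.significant) > 0
        lams.append(res.lambda_gc)
        p = res.table["p"].dropna().to_numpy()
        ks_ps.append(stats.kstest(p, "uniform").pvalue)
    assert with_hits <= 1
    assert 0.8 < np.median(lams) < 1.2
    assert np.median(ks_ps) > 0.01


def test_power_on_planted_qtl(sim, complete):
    """A QTL explaining 30% of the response variance at n ~ 140 is detected
    at the Bonferroni threshold 0.01/9828 in nearly every seed."""
    geno = complete
    n = geno.n_lines
    maf = geno.maf()
    candidates = np.flatnonzero(maf > 0.3)
    threshold = 0.01 / 9828
    detected = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        j = int(rng.choice(candidates))
        x = geno.dosage[:, j]
        xs = (x - x.mean()) / x.std()
        y = np.sqrt(0.30) * xs + np.sqrt(0.70) * rng.standard_normal(n)
        res = gw.association_scan(geno, y, covariates=None, alpha=0.01)
        detected += res.table["p"].iloc[j] < threshold
    assert detected >= 9


def test_bonferroni_cutoff_and_edge_cases():
    cutoff = 0.01 / 9828
    assert np.isclose(cutoff, 1.0175e-6, rtol=1e-3)
    hits = gw.bonferroni_hits(np.array([cutoff / 2, cutoff * 2, 0.5]),
                              alpha=0.01, m=9828)
    assert list(hits) == [0]
    assert gw.bonferroni_hits(np.array([]), alpha=0.01).size == 0
    assert gw.bonferroni_hits(np.ones(50), alpha=0.01).size == 0
    with pytest.raises(ValueError):
        gw.bonferroni_hits(np.array([0.5]), m=0)


def test_snp_identical_to_covariate_is_absorbed(scan_setup):
    geno = scan_setup["geno"].copy()
    cov = scan_setup["cov"]
    geno.dosage = geno.dosage.copy()
    # overwrite a marker with (a rescaled copy of) the first covariate
    snp = cov[:, 0] - cov[:, 0].min()
    geno.dosage[:, 0] = snp
    res = gw.association_scan(geno, scan_setup["y"], covariates=cov)
    # the residualized marker has no variance left: skipped, never significant
    assert np.isnan(res.table["p"].iloc[0]) or res.table["p"].iloc[0] > 0.5
    assert geno.markers["id"].iloc[0] not in set(res.significant["id"])


def test_scan_invariances(scan_setup):
    """P-values are invariant to marker order and to 0<->2 allele recoding;
    the effect changes sign under recoding."""
    geno, cov, y = scan_setup["geno"], scan_setup["cov"], scan_setup["y"]
    base = gw.association_scan(geno, y, covariates=cov)
    flipped = geno.copy()
    flipped.dosage = 2.0 - flipped.dosage
    res_f = gw.association_scan(flipped, y, covariates=cov)
    ok = ~base.table["p"].isna()
    assert np.allclose(base.table["p"][ok], res_f.table["p"][ok], rtol=1e-8)
    assert np.allclose(base.table["effect"][ok], -res_f.table["effect"][ok],
                       rtol=1e-8)

    rng = np.random.default_rng(1)
    perm = rng.permutation(geno.n_markers)
    shuffled = geno.subset(marker_mask=np.ones(geno.n_markers, bool))
    shuffled.dosage = geno.dosage[:, perm]
    shuffled.markers = geno.markers.iloc[perm].reset_index(drop=True)
    res_s = gw.association_scan(shuffled, y, covariates=cov)
    merged = base.table.set_index("id")["p"].reindex(res_s.table["id"])
    okm = ~merged.isna().to_numpy()
    assert np.allclose(merged.to_numpy()[okm],
                       res_s.table["p"].to_numpy()[okm], rtol=1e-8)


def test_collinear_covariates_rejected(scan_setup):
    cov = scan_setup["cov"]
    bad = np.column_stack([cov, cov[:, 0]])
    with pytest.raises(ValueError):
        gw.association_scan(scan_setup["geno"], scan_setup["y"], covariates=bad)


def test_explained_variance_accounting(scan_setup):
    geno, cov, y = scan_setup["geno"], scan_setup["cov"], scan_setup["y"]
    res = gw.association_scan(geno, y, covariates=cov)
    order = np.argsort(np.nan_to_num(res.table["p"].to_numpy(), nan=1.0))
    hits = order[:3]
    df, total = gw.explained_variance(geno, y, hits, covariates=cov)
    assert np.isclose(total, df["variance_pct"].sum())
    assert ((df["variance_pct"] >= 0) & (df["variance_pct"] <= 100)).all()
    # a response-independent SNP adds ~nothing
    rng = np.random.default_rng(2)
    null_y = rng.standard_normal(len(y))
    df0, total0 = gw.explained_variance(geno, null_y, hits[:1], covariates=cov)
    assert total0 < 8.0
    # empty hit set -> empty summary
    df_e, tot_e = gw.explained_variance(geno, y, np.array([], int), covariates=cov)
    assert tot_e == 0.0 and df_e.empty


def test_shared_qtl_tops_both_scans():
    """With a single planted flowering QTL, no environment-specific yield
    QTL, and the escape term carrying most of the stress-yield genetic
    variance, the same SNP tops the flowering and the stress-yield scans."""
    from lupinqg import containers, phenotype_met
    shared = 0
    n_seeds = 8
    for seed in range(120, 120 + n_seeds):
        _, geno, truth, plots = pipeline.simulate(
            seed, markers_per_chromosome=20, n_chromosomes=10,
            flowering_qtl_count=1, yield_qtl_count_per_env=0,
            trait_genetic_cv={"grain_yield": (20.0, 35.1),
                              "straw_biomass": (19.6, 30.4)},
            target_rg={"grain_yield": 0.6, "straw_biomass": 0.8,
                       "flowering_onset": 1.0},
            flowering_yieldF_gcorr=-0.3)
        complete = geno.copy()
        complete.dosage = truth.complete_dosage
        fl = containers.line_means(plots, "flowering_onset")
        ys = phenotype_met.blup_line_values(plots, "grain_yield", "stress")
        ids = list(geno.samples["id"])
        s1 = gw.association_scan(complete, fl.reindex(ids).to_numpy())
        s2 = gw.association_scan(complete, ys.reindex(ids).to_numpy())
        top1 = s1.table.loc[s1.table["p"].idxmin(), "id"]
        top2 = s2.table.loc[s2.table["p"].idxmin(), "id"]
        shared += top1 == top2
    assert shared >= int(0.8 * n_seeds)
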