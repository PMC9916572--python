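"""Whole-genome regression models: exact oracles, sampler calibration,
leakage guards, and cross-validation behaviour."""

import numpy as np
import pytest
from scipy import integrate

from lupinqg import genomic_prediction as gp
from lupinqg._reml import kernel_predict


@pytest.fixture(scope="module")
def marker_data(small_sim):
    truth = small_sim["truth"]
    W = truth.complete_dosage[:, :400].copy()
    keep = W.std(axis=0) > 0
    return W[:, keep]


def _polygenic_trait(W, h2, seed):
    rng = np.random.default_rng(seed)
    g = (W - W.mean(0)) @ rng.normal(size=W.shape[1])
    g = (g - g.mean()) / g.std()
    y = g + rng.normal(0, np.sqrt((1 - h2) / h2), W.shape[0])
    return g, y


# ---------------------------------------------------------------- kinship


def test_kinship_identity_weighting_is_plain_vanraden(marker_data):
    G = gp.kinship_vanraden(marker_data)
    G_w = gp.kinship_vanraden(marker_data, weights=np.ones(marker_data.shape[1]))
    assert np.allclose(G, G_w)


def test_kinship_duplicated_lines_identical_by_state(marker_data):
    W = np.vstack([marker_data, marker_data[:1]])
    G = gp.kinship_vanraden(W)
    n = marker_data.shape[0]
    assert np.isclose(G[0, n], G[0, 0])
    assert np.isclose(G[n, n], G[0, 0])


def test_kinship_psd(rng):
    W = rng.integers(0, 3, (20, 50)).astype(float)
    G = gp.kinship_vanraden(W)
    assert np.linalg.eigvalsh(G)[0] >= -1e-10
    assert np.allclose(G, G.T)


def test_pvalue_weights_contract():
    p = np.array([1e-8, 1e-3, 0.5, 1.0])
    d = gp.pvalue_weights(p)
    # -log10 transform normalized to mean 1 (before flooring), floored at 1e-3
    raw = -np.log10(p)
    assert np.allclose(np.maximum(raw / raw.mean(), 1e-3), d)
    assert d.min() >= 1e-3
    assert d[0] > d[1] > d[2]
    uniform = gp.pvalue_weights(np.full(10, 0.5))
    assert np.allclose(uniform, 1.0)


# ----------------------------------------------------------------- rrBLUP


def test_rrblup_noise_free_recovery(marker_data):
    W = marker_data[:, :50]
    rng = np.random.default_rng(0)
    beta = np.zeros(50)
    beta[[3, 17, 31]] = [0.8, -0.5, 0.6]
    y = 1.5 + (W - W.mean(0)) @ beta
    fit = gp.fit_rrblup(W, y)
    assert np.corrcoef(fit.predict(W), y)[0, 1] > 0.999


def test_rrblup_input_validation(marker_data):
    with pytest.raises(ValueError):
        gp.fit_rrblup(marker_data[:5], np.zeros(5))
    W0 = np.ones((20, 10))
    with pytest.raises(ValueError):
        gp.fit_rrblup(W0, np.arange(20.0))


def test_rrblup_equals_gblup_predictions(marker_data):
    """The classical equivalence: rrBLUP with K = WcWc' and GBLUP with the
    VanRaden G give identical predictions under matched REML components."""
    W = marker_data[:, :300]
    _, y = _polygenic_trait(W, 0.6, seed=1)
    tr, te = np.arange(100), np.arange(100, W.shape[0])
    fit = gp.fit_rrblup(W[tr], y[tr])
    pred_rr = fit.predict(W[te])

    Wc_all = W - W[tr].mean(0)
    p = W[tr].mean(0) / 2
    denom = 2 * np.sum(p * (1 - p))
    G_all = Wc_all @ Wc_all.T / denom
    res = gp.fit_gblup_reml(G_all[np.ix_(tr, tr)], y[tr])
    pred_g = kernel_predict(res, G_all[np.ix_(te, tr)])
    assert np.max(np.abs(pred_rr - pred_g)) < 1e-6


def test_rrblup_null_cross_validation_centered_on_zero(marker_data):
    rng = np.random.default_rng(5)
    y = rng.standard_normal(marker_data.shape[0])
    spec = gp.GsModelSpec(model="rrBLUP", seed=2)
    rep = gp.cross_validate(spec, marker_data, y, folds=5, repeats=2)
    assert abs(rep.mean) < 0.1


# ---------------------------------------------------------- Bayesian Lasso


def test_bl_fixed_seed_reproducible(marker_data):
    W = marker_data[:, :120]
    _, y = _polygenic_trait(W, 0.5, seed=2)
    f1 = gp.fit_bayesian_lasso(W, y, iterations=800, burn_in=100, seed=9)
    f2 = gp.fit_bayesian_lasso(W, y, iterations=800, burn_in=100, seed=9)
    assert np.array_equal(f1.q, f2.q)
    assert f1.sigma2 == f2.sigma2


def test_bl_shrinks_null_markers_harder_than_rrblup():
    """Sparse truth on unlinked markers: the double-exponential prior shrinks
    null markers more than ridge does, absolutely and relative to the causal
    effects it recovers."""
    rng = np.random.default_rng(3)
    n, m = 120, 500
    W = rng.binomial(2, 0.4, (n, m)).astype(float)
    causal = rng.choice(m, 5, replace=False)
    beta = np.zeros(m)
    beta[causal] = rng.choice([-1.0, 1.0], 5) * 1.2
    g = (W - W.mean(0)) @ beta
    y = g + rng.normal(0, 0.5 * g.std(), n)
    bl = gp.fit_bayesian_lasso(W, y, iterations=3000, burn_in=500, seed=4)
    rr = gp.fit_rrblup(W, y)
    null = np.setdiff1d(np.arange(m), causal)
    assert np.median(np.abs(bl.q[null])) / np.median(np.abs(rr.q[null])) < 1.0
    contrast_bl = np.median(np.abs(bl.q[null])) / np.median(np.abs(bl.q[causal]))
    contrast_rr = np.median(np.abs(rr.q[null])) / np.median(np.abs(rr.q[causal]))
    assert contrast_bl < contrast_rr


def test_bl_single_marker_matches_numeric_posterior():
    """Single-predictor subcase with fixed sigma2 and lambda2: the Gibbs
    posterior mean matches 1-D numeric integration of the Laplace-prior
    posterior."""
    rng = np.random.default_rng(6)
    n = 50
    x = rng.choice([0.0, 1.0, 2.0], n)
    xc = x - x.mean()
    beta_true = 0.5
    sigma2, lambda2 = 0.25, 4.0
    y = 1.0 + xc * beta_true + rng.normal(0, np.sqrt(sigma2), n)
    fit = gp.fit_bayesian_lasso(
        x[:, None], y, iterations=20_000, burn_in=2_000, seed=7,
        fix_sigma2=sigma2, fix_lambda2=lambda2)

    yc = y - y.mean()
    lam = np.sqrt(lambda2)

    def unnorm(b):
        return np.exp(-np.sum((yc - xc * b) ** 2) / (2 * sigma2)
                      - lam * abs(b) / np.sqrt(sigma2))

    z0, _ = integrate.quad(unnorm, -5, 5, limit=200)
    m1, _ = integrate.quad(lambda b: b * unnorm(b), -5, 5, limit=200)
    oracle = m1 / z0
    assert abs(fit.q[0] - oracle) < 0.02


def test_bl_divergence_detected(marker_data):
    W = marker_data[:, :50]
    y = np.full(W.shape[0], np.nan)
    with pytest.raises(Exception):
        gp.fit_bayesian_lasso(W, y, iterations=200, burn_in=50, seed=0)


# ------------------------------------------------------------ RKHS / GBLUP


def test_rkhs_gibbs_reproducible_and_interpolates(marker_data):
    W = marker_data[:, :300]
    g, _ = _polygenic_trait(W, 0.9, seed=8)
    G = gp.kinship_vanraden(W)
    y = g                                    # noise-free limit
    f1 = gp.fit_rkhs_gibbs(G, y, iterations=1500, burn_in=300, seed=3)
    f2 = gp.fit_rkhs_gibbs(G, y, iterations=1500, burn_in=300, seed=3)
    assert np.array_equal(f1.g, f2.g)
    assert np.corrcoef(f1.g, y - y.mean())[0, 1] > 0.99


def test_rkhs_rejects_non_psd():
    G = -np.eye(10)
    with pytest.raises(ValueError):
        gp.fit_rkhs_gibbs(G, np.zeros(10))


def test_rkhs_gibbs_close_to_exact_gblup(marker_data):
    W = marker_data[:, :300]
    _, y = _polygenic_trait(W, 0.6, seed=9)
    G = gp.kinship_vanraden(W)
    gibbs = gp.fit_rkhs_gibbs(G, y, iterations=4000, burn_in=500, seed=1)
    exact = gp.fit_gblup_reml(G, y)
    assert np.corrcoef(gibbs.g, exact.g_train)[0, 1] > 0.98


def test_gblup_cv_ability_band_at_h2_07(sim):
    """GBLUP cross-validated ability for a dense polygenic h2 = 0.7 trait on
    the factorial-cross population (band frozen from this design's
    Monte-Carlo behaviour)."""
    truth = sim["truth"]
    W = truth.complete_dosage
    G = gp.kinship_vanraden(W)
    n = W.shape[0]
    means = []
    for seed in range(4):
        _, y = _polygenic_trait(W, 0.7, seed=seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        rs = []
        for f in np.array_split(perm, 10):
            tr = np.setdiff1d(perm, f)
            res = gp.fit_gblup_reml(G[np.ix_(tr, tr)], y[tr])
            rs.append(np.corrcoef(kernel_predict(res, G[np.ix_(f, tr)]),
                                  y[f])[0, 1])
        means.append(np.mean(rs))
    assert 0.30 < np.mean(means) < 0.85


def test_ability_monotone_in_heritability(marker_data):
    W = marker_data[:, :300]
    abilities = []
    for h2 in (0.2, 0.5, 0.8):
        vals = []
        for seed in range(3):
            _, y = _polygenic_trait(W, h2, seed=seed)
            spec = gp.GsModelSpec(model="rrBLUP", seed=seed)
            rep = gp.cross_validate(spec, W, y, folds=5, repeats=1)
            vals.append(rep.mean)
        abilities.append(np.mean(vals))
    assert abilities[0] < abilities[1] < abilities[2]


# ----------------------------------------------------------------- WGBLUP


def test_wgblup_uniform_weights_equals_gblup(marker_data):
    W = marker_data[:, :200]
    _, y = _polygenic_trait(W, 0.6, seed=10)
    tr = np.arange(80)
    te = np.arange(80, W.shape[0])
    m = W.shape[1]
    fit_w, G_star = gp.fit_wgblup(
        W, y[tr], tr, pvalues=np.full(m, 0.3), pvalues_from_idx=tr,
        iterations=1000, burn_in=200, seed=5)
    G = gp.kinship_vanraden(W)
    assert np.allclose(G_star, G)
    fit_g = gp.fit_rkhs_gibbs(G[np.ix_(tr, tr)], y[tr],
                              iterations=1000, burn_in=200, seed=5)
    assert np.allclose(fit_w.g, fit_g.g)


def test_wgblup_leakage_guard():
    rng = np.random.default_rng(11)
    W = rng.integers(0, 3, (60, 100)).astype(float)
    y = rng.standard_normal(40)
    tr = np.arange(40)
    with pytest.raises(gp.LeakageError):
        gp.fit_wgblup(W, y, tr, pvalues=np.full(100, 0.5),
                      pvalues_from_idx=np.arange(60))   # includes validation lines
    with pytest.raises(gp.LeakageError):
        gp.fit_wgblup(W, y, tr, pvalues=np.full(100, 0.5),
                      pvalues_from_idx=None)


def test_wgblup_oracle_weight_advantage(marker_data):
    """With one large planted QTL, p-value weighting does not hurt and on
    average helps relative to unweighted GBLUP."""
    W = marker_data[:, :200]
    n, m = W.shape
    diffs = []
    for seed in range(6):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(m))
        x = W[:, j]
        if x.std() == 0:
            continue
        xs = (x - x.mean()) / x.std()
        y = np.sqrt(0.5) * xs + np.sqrt(0.5) * rng.standard_normal(n)
        tr = rng.permutation(n)[: int(0.8 * n)]
        te = np.setdiff1d(np.arange(n), tr)
        fit_w, G_star = gp.fit_wgblup(W, y[tr], tr, iterations=1200,
                                      burn_in=200, seed=seed)
        pred_w = fit_w.predict_new(G_star[np.ix_(te, tr)])
        G = gp.kinship_vanraden(W)
        fit_g = gp.fit_rkhs_gibbs(G[np.ix_(tr, tr)], y[tr], iterations=1200,
                                  burn_in=200, seed=seed)
        pred_g = fit_g.predict_new(G[np.ix_(te, tr)])
        diffs.append(np.corrcoef(pred_w, y[te])[0, 1]
                     - np.corrcoef(pred_g, y[te])[0, 1])
    assert np.mean(diffs) >= 0.0


# ------------------------------------------------------- cross-validation


def test_cv_near_perfect_for_deterministic_trait(marker_data):
    W = marker_data[:, :200]
    rng = np.random.default_rng(12)
    beta = np.zeros(200)
    beta[rng.choice(200, 5, replace=False)] = rng.normal(0, 1, 5)
    y = (W - W.mean(0)) @ beta
    spec = gp.GsModelSpec(model="rrBLUP", seed=3)
    rep = gp.cross_validate(spec, W, y, folds=10, repeats=1)
    assert rep.mean > 0.95


def test_cross_env_duplicate_environment_limit(marker_data):
    W = marker_data[:, :300]
    _, y = _polygenic_trait(W, 0.7, seed=13)
    spec = gp.GsModelSpec(model="rrBLUP", seed=4)
    ce = gp.cross_env_validate(spec, W, y, y, repeats=6)
    cv = gp.cross_validate(spec, W, y, folds=10, repeats=1)
    assert abs(ce.mean - cv.mean) < 0.2


def test_cross_env_attenuation_under_imperfect_rg(marker_data):
    """With genetic correlation 0.84 between environments, cross-environment
    ability falls below same-environment ability in nearly every seed."""
    W = marker_data[:, :300]
    n = W.shape[0]
    worse = 0
    n_seeds = 8
    for seed in range(n_seeds):
        rng = np.random.default_rng([21, seed])
        g1, y_a = _polygenic_trait(W, 0.7, seed=100 + seed)
        g2, _ = _polygenic_trait(W, 0.7, seed=200 + seed)
        g_b = 0.84 * g1 + np.sqrt(1 - 0.84 ** 2) * g2
        y_b = g_b + rng.normal(0, np.sqrt(0.3 / 0.7), n)
        spec = gp.GsModelSpec(model="rrBLUP", seed=seed)
        same = gp.cross_validate(spec, W, y_b, folds=10, repeats=1).mean
        cross = gp.cross_env_validate(spec, W, y_a, y_b, repeats=10).mean
        worse += cross < same
    assert worse >= n_seeds - 1


def test_cross_env_null_when_rg_zero(marker_data):
    W = marker_data[:, :300]
    n = W.shape[0]
    vals = []
    for seed in range(5):
        rng = np.random.default_rng([31, seed])
        _, y_a = _polygenic_trait(W, 0.7, seed=300 + seed)
        g2, _ = _polygenic_trait(W, 0.7, seed=400 + seed)
        y_b = g2 + rng.normal(0, np.sqrt(0.3 / 0.7), n)
        spec = gp.GsModelSpec(model="rrBLUP", seed=seed)
        vals.append(gp.cross_env_validate(spec, W, y_a, y_b, repeats=6).mean)
    assert abs(np.mean(vals)) < 0.15


def test_cross_env_requires_matching_line_sets(marker_data):
    spec = gp.GsModelSpec(model="rrBLUP")
    with pytest.raises(ValueError):
        gp.cross_env_validate(spec, marker_data, np.zeros(10), np.zeros(12))


def test_model_spec_validation():
    with pytest.raises(ValueError):
        gp.GsModelSpec(model="BayesZ")
    with pytest.raises(ValueError):
        gp.GsModelSpec(gibbs_iterations=100, gibbs_burn_in=200)
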