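"""QC filtering order and idempotence, heterozygosity screening, imputation
accuracy, and LD-decay behaviour on constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from lupinqg import marker_qc_ld as qc
from lupinqg.containers import GenotypeMatrix


def _make_geno(dosage, positions=None, chrom="Chr01"):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    pos = np.arange(1, m + 1) * 100 if positions is None else np.asarray(positions)
    markers = pd.DataFrame({"id": [f"{chrom}_{p}" for p in pos],
                            "chrom": chrom, "pos": pos})
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(n)]})
    return GenotypeMatrix(dosage, markers, samples)


def test_filter_cascade_counts():
    """Hand-countable toy: 3 low-MAF + 2 high-missingness markers (disjoint)
    drop out of 10."""
    rng = np.random.default_rng(0)
    n = 40
    cols = []
    for j in range(5):                       # 5 clean markers, MAF ~0.4
        cols.append(rng.choice([0, 2], n, p=[0.6, 0.4]).astype(float))
    for j in range(3):                       # 3 markers below MAF 0.05
        c = np.zeros(n)
        c[0] = 2.0
        cols.append(c)
    for j in range(2):                       # 2 markers above 30% missing
        c = rng.choice([0, 2], n, p=[0.5, 0.5]).astype(float)
        c[: int(0.4 * n)] = np.nan
        cols.append(c)
    geno = _make_geno(np.column_stack(cols))
    out = qc.filter_markers_samples(geno, maf_min=0.05, miss_marker_max=0.30)
    assert out.n_markers == 5


def test_permissive_thresholds_only_drop_monomorphic():
    rng = np.random.default_rng(1)
    dosage = rng.choice([0, 1, 2], (30, 8)).astype(float)
    dosage[:, 3] = 2.0                        # monomorphic
    geno = _make_geno(dosage)
    out = qc.filter_markers_samples(geno, maf_min=0.0, miss_marker_max=1.0)
    assert out.n_markers == 7


def test_sample_missingness_threshold():
    rng = np.random.default_rng(2)
    dosage = rng.choice([0, 2], (10, 20)).astype(float)
    dosage[0, :12] = np.nan                   # 60% missing sample
    geno = _make_geno(dosage)
    out = qc.filter_markers_samples(geno, maf_min=0.0, miss_marker_max=1.0,
                                    miss_sample_max=0.50)
    assert out.n_lines == 9
    assert "s0" not in list(out.samples["id"])


def test_filtering_idempotent(sim):
    once = qc.filter_markers_samples(sim["geno"])
    twice = qc.filter_markers_samples(once)
    assert once.n_markers == twice.n_markers
    assert once.n_lines == twice.n_lines


def test_het_excess_no_removal_when_uniform():
    dosage = np.tile([0.0, 1.0, 2.0, 0.0], (12, 5)).T[:12, :5]
    rng = np.random.default_rng(3)
    dosage = rng.choice([0, 2], (12, 5)).astype(float)
    geno = _make_geno(dosage)
    out = qc.filter_het_excess(geno)          # all het rates zero -> zero SD
    assert out.n_markers == 5 and out.n_lines == 12


def test_het_excess_removes_constructed_outlier():
    rng = np.random.default_rng(4)
    n, m = 60, 100
    dosage = rng.choice([0, 2], (n, m), p=[0.5, 0.5]).astype(float)
    het_mask = rng.random((n, m)) < 0.05      # background het ~5%
    dosage[het_mask] = 1.0
    dosage[:, 7] = 1.0                        # fully heterozygous marker
    geno = _make_geno(dosage)
    out = qc.filter_het_excess(geno)
    assert geno.markers["id"].iloc[7] not in set(out.markers["id"])
    assert out.n_markers >= m - 3


def test_f5_marker_het_rate_near_ssd_expectation(sim):
    """At F1-segregating loci the SSD expectation is (1/2)^4; the genome-wide
    marker mean is that value scaled by the segregation probability."""
    het = sim["truth"].het_by_generation[-1]
    assert abs(het - 0.0625) < 0.01
    mean_marker_het = np.nanmean(sim["geno"].marker_het_rate())
    assert 0.005 < mean_marker_het < 0.0625


def test_impute_identity_when_complete():
    rng = np.random.default_rng(5)
    dosage = rng.choice([0, 1, 2], (20, 15)).astype(float)
    geno = _make_geno(dosage)
    for method in ("mode", "knn"):
        out = qc.impute_missing(geno, method=method, seed=0)
        assert np.array_equal(out.dosage, dosage)


def test_impute_never_alters_observed_calls(sim):
    sub = sim["geno"].subset(marker_mask=np.arange(sim["geno"].n_markers) < 120)
    obs = ~np.isnan(sub.dosage)
    out = qc.impute_missing(sub, method="knn", seed=1)
    assert np.array_equal(out.dosage[obs], sub.dosage[obs])
    assert not np.isnan(out.dosage).any()
    assert np.isin(out.dosage, [0.0, 1.0, 2.0]).all()


def test_all_missing_marker_rejected():
    dosage = np.array([[0, np.nan], [2, np.nan], [0, np.nan]], float)
    geno = _make_geno(dosage)
    with pytest.raises(ValueError):
        qc.impute_missing(geno, method="mode")


def test_mask_and_recover_accuracy(sim):
    """5% MCAR masking: rf-like and knn beat mode imputation, all above 0.7
    accuracy on family-structured genotypes."""
    truth = sim["truth"]
    keep = np.arange(150)
    complete = truth.complete_dosage[:, keep]
    base = _make_geno(complete)
    acc = {"mode": [], "knn": [], "rf-like": []}
    for seed in range(3):
        rng = np.random.default_rng(seed)
        mask = rng.random(complete.shape) < 0.05
        masked = complete.copy()
        masked[mask] = np.nan
        geno = _make_geno(masked)
        for method in acc:
            out = qc.impute_missing(geno, method=method, seed=seed,
                                    rf_trees=50)
            acc[method].append((out.dosage[mask] == complete[mask]).mean())
    assert np.mean(acc["rf-like"]) > np.mean(acc["mode"])
    assert np.mean(acc["knn"]) > np.mean(acc["mode"])
    assert np.mean(acc["rf-like"]) > 0.7 and np.mean(acc["knn"]) > 0.7


def test_knn_imputes_family_consensus():
    """A missing call in a family-monomorphic column goes to the family
    allele: nearest neighbours are the family mates."""
    n_fam, fam_size, m = 4, 8, 30
    rng = np.random.default_rng(9)
    fam_alleles = rng.choice([0, 2], (n_fam, m)).astype(float)
    dosage = np.repeat(fam_alleles, fam_size, axis=0)
    dosage += 0.0
    geno = _make_geno(dosage.copy())
    geno.dosage[0, 5] = np.nan
    out = qc.impute_missing(geno, method="knn", seed=0)
    assert out.dosage[0, 5] == fam_alleles[0, 5]


def test_ld_duplicated_marker_r2_one():
    rng = np.random.default_rng(10)
    a = rng.choice([0, 2], 50).astype(float)
    b = rng.choice([0, 2], 50).astype(float)
    dosage = np.column_stack([a, a, b])
    geno = _make_geno(dosage, positions=[100, 600, 40_000])
    curve = qc.ld_decay(geno, window=50_000)
    pairs = curve.per_chromosome["Chr01"]
    dup = pairs[pairs["dist_bp"] == 500]
    assert np.isclose(dup["r2"].iloc[0], 1.0)
    assert ((pairs["r2"] >= 0) & (pairs["r2"] <= 1.0 + 1e-12)).all()


def test_ld_permutation_null_floor(sim, rng):
    """Independently permuted columns leave only the ~1/(n-1) small-sample
    r2 floor."""
    complete = sim["truth"].complete_dosage[:, :80].copy()
    n = complete.shape[0]
    for j in range(complete.shape[1]):
        rng.shuffle(complete[:, j])
    geno = _make_geno(complete, positions=np.arange(1, 81) * 500)
    curve = qc.ld_decay(geno, window=50_000)
    mean_r2 = curve.per_chromosome["Chr01"]["r2"].mean()
    assert mean_r2 < 3.0 / (n - 1)


def test_ld_block_fixture_half_decay_inside_block():
    """A tight-linkage block among free markers puts the half-decay distance
    within the block length."""
    rng = np.random.default_rng(12)
    n = 80
    block_len = 5_000
    anchor = rng.choice([0, 2], n).astype(float)
    cols, pos = [], []
    for k in range(6):                       # tight block: correlated copies
        c = anchor.copy()
        flip = rng.random(n) < 0.05 * k
        c[flip] = 2 - c[flip]
        cols.append(c)
        pos.append(1 + k * 1_000)
    for k in range(8):                       # free markers farther away
        cols.append(rng.choice([0, 2], n).astype(float))
        pos.append(10_000 + k * 4_000)
    geno = _make_geno(np.column_stack(cols), positions=pos)
    curve = qc.ld_decay(geno, window=50_000)
    half = curve.half_decay_bp["Chr01"]
    assert np.isfinite(half)
    # the smoothed fit crosses the half level between the end of the block
    # and the first free marker
    assert half <= 10_000
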