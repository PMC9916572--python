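"""Synthetic factorial-cross inbred-line population with known ground truth.

The generator emulates the statistical structure of a two-environment managed
drought trial on white lupin inbred lines:

* 4 sweet-seed x 4 bitter-seed parents crossed factorially (16 families),
  each line descended from one F1 by four rounds of single-seed-descent
  selfing with recombination, leaving ~6.25% residual heterozygosity;
* biallelic SNPs on 25 chromosomes with family-structured allele sharing, so
  that clustering on principal components recovers the cross families;
* plot-level phenotypes (grain yield, straw biomass, onset of flowering) in a
  drought-stressed and a moisture-favourable environment with 4 complete
  blocks each, calibrated to target means, genetic CVs, heritabilities and
  cross-environment genetic correlations;
* a linear drought-escape effect of flowering time on stress yield
  (default -0.036 t/ha per day of delayed flowering).

Ground truth (QTL positions, breeding values, variance components) is
returned alongside, for parameter-recovery testing downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, write_pheno_csv, write_vcf, write_json

TRAITS = ("grain_yield", "straw_biomass", "flowering_onset")


@dataclasses.dataclass
class SimulationConfig:
    """Study-design and calibration parameters for the generator.

    Trait calibration defaults reproduce the trial's reported scale: grain
    yield means 0.88 / 2.28 t/ha (stress / favourable) with genetic CVs of
    28.7 / 35.1 % and H2 of 0.70 / 0.69; straw biomass 2.25 / 6.85 t/ha,
    CVs 19.6 / 30.4 %, H2 0.65 / 0.72; onset of flowering 38.7 / 41.5 days
    from 1 April with a common genetic variance of 19.98 d2 (r_g = 1) and H2
    0.93 / 0.92.  The cross-environment genetic correlation target for grain
    yield is 0.84.
    """

    n_parents_sweet: int = 4
    n_parents_bitter: int = 4
    lines_per_cross: int = 9
    n_chromosomes: int = 25
    markers_per_chromosome: int = 400
    chromosome_length_bp: int = 20_000_000
    n_blocks: int = 4
    selfing_generations: int = 4
    crossover_mean: float = 1.5          # per chromosome per meiosis, >=1 obligate
    trait_means: dict = dataclasses.field(default_factory=lambda: {
        "grain_yield": (0.88, 2.28),
        "straw_biomass": (2.25, 6.85),
        "flowering_onset": (38.7, 41.5),
    })
    trait_genetic_cv: dict = dataclasses.field(default_factory=lambda: {
        "grain_yield": (28.7, 35.1),
        "straw_biomass": (19.6, 30.4),
    })
    flowering_genetic_var: float = 19.98   # d^2, shared across environments
    target_H2: dict = dataclasses.field(default_factory=lambda: {
        ("grain_yield", "stress"): 0.70,
        ("grain_yield", "favourable"): 0.69,
        ("straw_biomass", "stress"): 0.65,
        ("straw_biomass", "favourable"): 0.72,
        ("flowering_onset", "stress"): 0.93,
        ("flowering_onset", "favourable"): 0.92,
    })
    target_rg: dict = dataclasses.field(default_factory=lambda: {
        "grain_yield": 0.84,
        "straw_biomass": 0.93,
        "flowering_onset": 1.0,
    })
    escape_slope: float = -0.036          # t/ha per day
    flowering_yieldF_gcorr: float = -0.50  # genetic corr flowering ~ favourable yield
    straw_yield_gcorr: float = 0.60        # genetic corr straw ~ same-env yield
    flowering_qtl_count: int = 7
    yield_qtl_count_per_env: int = 2
    missing_rate: float = 0.10
    maf_floor: float = 0.05
    block_var_frac: float = 0.25          # block variance as fraction of error variance
    seed: int = 0

    @property
    def environments(self):
        return ("stress", "favourable")

    def validate(self) -> None:
        counts = dict(
            n_parents_sweet=self.n_parents_sweet,
            n_parents_bitter=self.n_parents_bitter,
            lines_per_cross=self.lines_per_cross,
            n_chromosomes=self.n_chromosomes,
            markers_per_chromosome=self.markers_per_chromosome,
            chromosome_length_bp=self.chromosome_length_bp,
            n_blocks=self.n_blocks,
            selfing_generations=self.selfing_generations,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.maf_floor >= 0.5:
            raise ValueError("maf_floor must be < 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for key, h2 in self.target_H2.items():
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"target H2 out of [0,1] for {key}")
        for t, rg in self.target_rg.items():
            if not -1.0 <= rg <= 1.0:
                raise ValueError(f"target r_g out of [-1,1] for {t}")
        if self.flowering_genetic_var < 0:
            raise ValueError("flowering_genetic_var must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Truth record filled during population and phenotype simulation."""

    complete_dosage: np.ndarray
    qtl: pd.DataFrame                       # marker_idx, id, chrom, pos, trait, environment, var_frac
    het_by_generation: np.ndarray           # mean het among F1-segregating loci, F1..F(1+g)
    true_variance_components: dict = dataclasses.field(default_factory=dict)
    true_rg: dict = dataclasses.field(default_factory=dict)
    line_breeding_values: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------


def _gamete(h1: np.ndarray, h2: np.ndarray, pos: np.ndarray, length: int,
            crossover_mean: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete; crossover count is 1 + Poisson(mean - 1)."""
    n_xo = 1 + rng.poisson(max(crossover_mean - 1.0, 0.0))
    xo = np.sort(rng.uniform(0, length, n_xo))
    seg = (int(rng.integers(2)) + np.searchsorted(xo, pos)) % 2
    return np.where(seg == 0, h1, h2)


def simulate_population(config: SimulationConfig):
    """Simulate F5 inbred-line genotypes for the 16-family factorial cross.

    Returns
    -------
    geno : GenotypeMatrix
        Dosages with missing calls injected completely at random.
    truth : GroundTruth
        Complete dosages, QTL map, and per-generation heterozygosity.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    n_chr = config.n_chromosomes
    m_per = config.markers_per_chromosome
    L = config.chromosome_length_bp

    # marker map
    chrom_names = [f"Chr{c + 1:02d}" for c in range(n_chr)]
    pos_by_chr = [
        np.sort(rng.choice(L - 1, size=m_per, replace=False)) + 1
        for _ in range(n_chr)
    ]

    # parent genomes: homozygous alleles drawn from a Beta(0.5, 0.5) base
    # frequency per marker, independently per parent -> both within- and
    # between-family polymorphism
    n_par = config.n_parents_sweet + config.n_parents_bitter
    base_p = [np.clip(rng.beta(0.5, 0.5, m_per), 0.02, 0.98) for _ in range(n_chr)]
    parent_alleles = [
        (rng.random((n_par, m_per)) < p).astype(np.int8) for p in base_p
    ]

    crosses = [
        (s, config.n_parents_sweet + b)
        for s in range(config.n_parents_sweet)
        for b in range(config.n_parents_bitter)
    ]
    n_lines = len(crosses) * config.lines_per_cross

    dosage = np.empty((n_lines, n_chr * m_per), dtype=float)
    line_ids, cross_ids = [], []
    n_gen = config.selfing_generations
    het_num = np.zeros(n_gen + 1)
    het_den = np.zeros(n_gen + 1)

    li = 0
    for ci, (ps, pb) in enumerate(crosses):
        cross_name = f"S{ps + 1}xB{pb - config.n_parents_sweet + 1}"
        for k in range(config.lines_per_cross):
            cols = []
            for c in range(n_chr):
                pos = pos_by_chr[c]
                seg = parent_alleles[c][ps] != parent_alleles[c][pb]
                h1 = np.zeros(m_per, dtype=np.int8)   # 0 = sweet-parent origin
                h2 = np.ones(m_per, dtype=np.int8)    # 1 = bitter-parent origin
                het_num[0] += np.count_nonzero(seg)   # F1 het at all seg loci
                het_den[0] += np.count_nonzero(seg)
                for gen in range(1, n_gen + 1):
                    g1 = _gamete(h1, h2, pos, L, config.crossover_mean, rng)
                    g2 = _gamete(h1, h2, pos, L, config.crossover_mean, rng)
                    h1, h2 = g1, g2
                    het_num[gen] += np.count_nonzero((h1 != h2) & seg)
                    het_den[gen] += np.count_nonzero(seg)
                a1 = np.where(h1 == 0, parent_alleles[c][ps], parent_alleles[c][pb])
                a2 = np.where(h2 == 0, parent_alleles[c][ps], parent_alleles[c][pb])
                cols.append((a1 + a2).astype(float))
            dosage[li] = np.concatenate(cols)
            line_ids.append(f"L{li + 1:03d}")
            cross_ids.append(cross_name)
            li += 1

    markers = pd.DataFrame({
        "id": [f"{chrom_names[c]}_{p}" for c in range(n_chr) for p in pos_by_chr[c]],
        "chrom": np.repeat(chrom_names, m_per),
        "pos": np.concatenate(pos_by_chr),
    })
    samples = pd.DataFrame({"id": line_ids, "cross_id": cross_ids})

    # enforce the MAF floor on the realized population
    p_hat = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep = maf >= config.maf_floor
    dosage = dosage[:, keep]
    markers = markers.loc[keep].reset_index(drop=True)

    complete = dosage.copy()

    # MCAR missingness
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage = dosage.copy()
        dosage[mask] = np.nan

    geno = GenotypeMatrix(dosage, markers, samples)
    qtl = _select_qtl(markers, complete, config, rng)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_curve = het_num / het_den
    truth = GroundTruth(complete_dosage=complete, qtl=qtl,
                        het_by_generation=het_curve)
    return geno, truth


def _select_qtl(markers: pd.DataFrame, complete: np.ndarray,
                config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pick QTL markers (MAF >= 0.2, spread over chromosomes) and variance shares."""
    p = complete.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    eligible = np.flatnonzero(maf >= 0.2)
    rng.shuffle(eligible)

    used_chrom: set[str] = set()
    picked: list[int] = []

    def take(n: int) -> list[int]:
        out = []
        for idx in eligible:
            if len(out) == n:
                break
            ch = markers["chrom"].iat[idx]
            if idx in picked or ch in used_chrom:
                continue
            out.append(int(idx))
            picked.append(int(idx))
            used_chrom.add(ch)
        # fall back to reusing chromosomes if the genome is small
        for idx in eligible:
            if len(out) == n:
                break
            if idx not in picked:
                out.append(int(idx))
                picked.append(int(idx))
        return out

    rows = []
    # flowering QTL variance shares decline geometrically; jointly ~55% of the
    # flowering genetic variance, the top one ~20%
    n_f = config.flowering_qtl_count
    shares = 0.20 * 0.7 ** np.arange(n_f)
    shares *= 0.55 / shares.sum()
    for idx, fr in zip(take(n_f), shares):
        rows.append((idx, "flowering_onset", "both", float(fr)))
    ny = config.yield_qtl_count_per_env
    yshare = np.array([0.15, 0.08][:ny] + [0.05] * max(ny - 2, 0))
    for env in ("stress", "favourable"):
        for idx, fr in zip(take(ny), yshare):
            rows.append((idx, "grain_yield", env, float(fr)))
    qtl = pd.DataFrame(rows, columns=["marker_idx", "trait", "environment", "var_frac"])
    qtl["id"] = markers["id"].iloc[qtl["marker_idx"]].to_numpy()
    qtl["chrom"] = markers["chrom"].iloc[qtl["marker_idx"]].to_numpy()
    qtl["pos"] = markers["pos"].iloc[qtl["marker_idx"]].to_numpy()
    return qtl


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def _std(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("degenerate (zero-variance) genetic score")
    return (v - v.mean()) / s


def _residualize(v: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    for o in others:
        v = v - (v @ o) / (o @ o) * o
    return v


def _poly_score(Xs: np.ndarray, qtl_idx: np.ndarray, qtl_frac: np.ndarray,
                rng: np.random.Generator, n_poly: int = 300) -> np.ndarray:
    """Standardized genetic score: planted QTL shares + a polygenic tail."""
    n, m = Xs.shape
    poly_idx = rng.choice(m, size=min(n_poly, m), replace=False)
    poly = Xs[:, poly_idx] @ rng.normal(size=poly_idx.size)
    poly = _std(poly)
    total_qtl = float(np.sum(qtl_frac))
    score = np.sqrt(max(1.0 - total_qtl, 0.0)) * poly
    for idx, fr in zip(qtl_idx, qtl_frac):
        score = score + np.sqrt(fr) * Xs[:, idx]
    return _std(score)


def simulate_phenotypes(geno: GenotypeMatrix, truth: GroundTruth,
                        config: SimulationConfig) -> pd.DataFrame:
    """Simulate balanced plot-level phenotypes and fill the truth record.

    The genetic architecture is built from standardized, in-sample
    orthogonalized marker scores so that realized breeding-value variances and
    correlations hit the configured targets exactly; sampling noise then
    enters only through block and plot errors.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    X = truth.complete_dosage
    n = X.shape[0]
    sd = X.std(axis=0)
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]

    q = truth.qtl
    qf = q[q["trait"] == "flowering_onset"]
    qys = q[(q["trait"] == "grain_yield") & (q["environment"] == "stress")]
    qyf = q[(q["trait"] == "grain_yield") & (q["environment"] == "favourable")]

    z_flow = _poly_score(Xs, qf["marker_idx"].to_numpy(), qf["var_frac"].to_numpy(), rng)
    z_tol = _std(_residualize(
        _poly_score(Xs, qys["marker_idx"].to_numpy(), qys["var_frac"].to_numpy(), rng),
        [z_flow]))
    z_spec = _std(_residualize(
        _poly_score(Xs, qyf["marker_idx"].to_numpy(), qyf["var_frac"].to_numpy(), rng),
        [z_flow, z_tol]))
    none = np.empty(0, int)
    z_straw_c = _std(_residualize(_poly_score(Xs, none, none, rng),
                                  [z_flow, z_tol, z_spec]))
    z_straw_s = _std(_residualize(_poly_score(Xs, none, none, rng),
                                  [z_flow, z_tol, z_spec, z_straw_c]))
    z_straw_f = _std(_residualize(_poly_score(Xs, none, none, rng),
                                  [z_flow, z_tol, z_spec, z_straw_c, z_straw_s]))

    # --- target scales ---------------------------------------------------
    mean_ys, mean_yf = config.trait_means["grain_yield"]
    mean_ss, mean_sf = config.trait_means["straw_biomass"]
    mean_fs, mean_ff = config.trait_means["flowering_onset"]
    cv_ys, cv_yf = config.trait_genetic_cv["grain_yield"]
    cv_ss, cv_sf = config.trait_genetic_cv["straw_biomass"]

    s_flow = np.sqrt(config.flowering_genetic_var)
    s_gys = cv_ys / 100.0 * mean_ys
    s_gyf = cv_yf / 100.0 * mean_yf
    s_gss = cv_ss / 100.0 * mean_ss
    s_gsf = cv_sf / 100.0 * mean_sf

    a1 = config.escape_slope * s_flow
    if abs(a1) >= mean_ys:
        raise ValueError("escape term alone exceeds the stress yield mean; "
                         "configuration would produce negative expected yields")
    if a1 ** 2 > s_gys ** 2:
        raise ValueError("escape variance exceeds the target stress-yield "
                         "genetic variance; reduce |escape_slope| or flowering variance")
    c_s = np.sqrt(s_gys ** 2 - a1 ** 2)

    rg_y = config.target_rg["grain_yield"]
    a2 = config.flowering_yieldF_gcorr * s_gyf
    c2 = (rg_y * s_gys * s_gyf - a1 * a2) / c_s
    d2sq = s_gyf ** 2 - a2 ** 2 - c2 ** 2
    if d2sq < 0:
        raise ValueError("infeasible yield genetic-correlation targets "
                         f"(residual variance {d2sq:.4f} < 0)")
    d2 = np.sqrt(d2sq)

    u_flow = s_flow * z_flow
    u_ys = a1 * z_flow + c_s * z_tol
    u_yf = a2 * z_flow + c2 * z_tol + d2 * z_spec

    rho = config.straw_yield_gcorr
    rg_s = config.target_rg["straw_biomass"]
    kappa = (rg_s - rho ** 2 * rg_y) / (1.0 - rho ** 2)
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("straw genetic-correlation targets infeasible with "
                         f"straw_yield_gcorr={rho} (kappa={kappa:.3f})")
    zy_s = u_ys / s_gys
    zy_f = u_yf / s_gyf
    base_c = np.sqrt(kappa) * z_straw_c
    u_ss = s_gss * (rho * zy_s + np.sqrt(1 - rho ** 2) * (base_c + np.sqrt(1 - kappa) * z_straw_s))
    u_sf = s_gsf * (rho * zy_f + np.sqrt(1 - rho ** 2) * (base_c + np.sqrt(1 - kappa) * z_straw_f))

    bv = {
        ("grain_yield", "stress"): mean_ys + u_ys,
        ("grain_yield", "favourable"): mean_yf + u_yf,
        ("straw_biomass", "stress"): mean_ss + u_ss,
        ("straw_biomass", "favourable"): mean_sf + u_sf,
        ("flowering_onset", "stress"): mean_fs + u_flow,
        ("flowering_onset", "favourable"): mean_ff + u_flow,
    }
    gvar = {
        ("grain_yield", "stress"): s_gys ** 2,
        ("grain_yield", "favourable"): s_gyf ** 2,
        ("straw_biomass", "stress"): s_gss ** 2,
        ("straw_biomass", "favourable"): s_gsf ** 2,
        ("flowering_onset", "stress"): s_flow ** 2,
        ("flowering_onset", "favourable"): s_flow ** 2,
    }

    # --- plot-level table -------------------------------------------------
    records = []
    n_trunc = 0
    for env_i, env in enumerate(config.environments):
        errs, blocks = {}, {}
        for trait in TRAITS:
            h2 = config.target_H2[(trait, env)]
            s2g = gvar[(trait, env)]
            s2e = (config.n_blocks * s2g * (1 - h2) / h2) if h2 > 0 else s2g
            errs[trait] = np.sqrt(s2e)
            blocks[trait] = rng.normal(0.0, np.sqrt(config.block_var_frac * s2e),
                                       config.n_blocks)
        for b in range(config.n_blocks):
            vals = {}
            for trait in TRAITS:
                y = bv[(trait, env)] + blocks[trait][b] + rng.normal(0, errs[trait], n)
                if trait != "flowering_onset":
                    neg = y < 0
                    n_trunc += int(neg.sum())
                    y = np.where(neg, 0.0, y)
                vals[trait] = y
            for i in range(n):
                records.append((
                    geno.samples["id"].iat[i], geno.samples["cross_id"].iat[i],
                    env, b + 1,
                    vals["grain_yield"][i], vals["straw_biomass"][i],
                    vals["flowering_onset"][i],
                ))
    if n_trunc:
        warnings.warn(f"truncated {n_trunc} negative simulated yield/biomass "
                      "plot values at zero")

    plots = pd.DataFrame(records, columns=[
        "line_id", "cross_id", "environment", "block",
        "grain_yield", "straw_biomass", "flowering_onset",
    ])

    # --- fill truth -------------------------------------------------------
    bv_rows = []
    for (trait, env), v in bv.items():
        for i in range(n):
            bv_rows.append((geno.samples["id"].iat[i], trait, env, v[i]))
    truth.line_breeding_values = pd.DataFrame(
        bv_rows, columns=["line_id", "trait", "environment", "breeding_value"])
    for (trait, env) in gvar:
        h2 = config.target_H2[(trait, env)]
        s2g = gvar[(trait, env)]
        s2e = (config.n_blocks * s2g * (1 - h2) / h2) if h2 > 0 else s2g
        truth.true_variance_components[f"{trait}|{env}"] = {
            "s2_g": s2g, "s2_e": s2e,
            "s2_block": config.block_var_frac * s2e, "H2": h2,
        }
    truth.true_rg = dict(config.target_rg)
    return plots


# ---------------------------------------------------------------------------
# convenience output
# ---------------------------------------------------------------------------


def write_outputs(geno: GenotypeMatrix, truth: GroundTruth,
                  plots: pd.DataFrame, outdir: str | Path) -> None:
    """Write genotypes (VCF), phenotypes (tidy CSV) and truth (JSON/CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(geno, outdir / "genotypes.vcf")
    write_pheno_csv(plots, outdir / "phenotypes.csv")
    truth.qtl.to_csv(outdir / "truth_qtl.csv", index=False)
    truth.line_breeding_values.to_csv(outdir / "truth_breeding_values.csv", index=False)
    write_json({
        "true_variance_components": truth.true_variance_components,
        "true_rg": truth.true_rg,
        "het_by_generation": truth.het_by_generation,
    }, outdir / "truth_summary.json")
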