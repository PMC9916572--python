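# Methods

`lupinqg` implements the complete quantitative-genetics analysis chain of a
two-environment managed drought trial on white lupin inbred lines, together
with a synthetic-population generator that reproduces the trial's statistical
structure with known ground truth. This note documents the models, the
generator, the numerical choices, and the limits of what the test suite can
show.

## The study design being modelled

A reference population of F5 inbred lines from a 4 x 4 factorial cross
(four sweet-seed elite parents x four bitter-seed landrace parents, 16
families) is evaluated in two managed environments — severe terminal drought
("stress") and moisture-favourable — each with 4 complete blocks. Traits are
plot-level grain yield (t/ha), straw biomass (t/ha), and onset of flowering
(days from 1 April); aerial biomass and harvest index (grain / aerial
biomass) are derived. Lines are genotyped at thousands of mapped biallelic
SNPs on 25 chromosomes.

## Multi-environment statistics (`phenotype_met`)

Per environment, the plot model is `y_ib = mu + g_i + b_b + e_ib`. Variance
components are estimated by REML (profile log-likelihood, components bounded
at zero, L-BFGS-B to a 1e-8 function tolerance; negative solutions are
clamped and flagged); genotype significance uses the fixed-genotype balanced
ANOVA F test. On balanced data the REML solutions coincide with the ANOVA
moment estimators `(MS_G - MS_E)/n` whenever the latter are non-negative —
this equivalence is the module's numerical oracle.

Derived statistics:

* genetic coefficient of variation `CV = 100 * s_g / m`;
* broad-sense heritability on a line-mean basis
  `H2 = s2_g / (s2_g + s2_e / n)` with `n` the number of blocks. Its
  standard error uses the balanced-design identity `H2 = 1 - MSE/MSG` and a
  delta-method approximation, `SE = (1 - H2) * sqrt(2/df_G + 2/df_E)`,
  which reproduces the magnitude of SEs customarily reported for trials of
  this size (~0.04 at H2 = 0.7 with 138 lines x 4 blocks);
* BLUPs as heritability-shrunken line means,
  `BLUP_i = m + H2 (mean_i - m)` — the standard two-stage preparation of a
  genomic-selection response variable.

The combined model adds a genotype-x-environment random term with
environment fixed and blocks nested in environments. The genetic
correlation of a trait across the two environments defaults to the
Burdon-type heritability-corrected phenotypic correlation of line means,
`r_g = corr(m_1, m_2) / sqrt(H2_1 H2_2)`, truncated to [-1, 1] with a flag.
The homogeneous-variance alternative `s2_G / (s2_G + s2_GEI)` is selectable;
it is exact when genotypic variance is homogeneous across environments
(e.g. it returns exactly 1 when the GEI component is zero) but understates
`r_g` under variance heterogeneity, which is why it is not the default.
The SE of `r_g` is a nonparametric bootstrap over lines (1000 resamples by
default; components inside the bootstrap use the fast balanced moment
forms). Consistency with unity is tested by the t-based confidence interval
`r_g +/- t_{df, 0.975} SE`.

## Drought escape and susceptibility (`escape_drought`)

Line-mean grain yield under stress is regressed on line-mean flowering
(averaged over environments, justified by the absence of G x E for
flowering). The escape slope, intercept and R2 always refer to the linear
fit; a quadratic term is screened at p < 0.05 and, when significant, defines
the adjustment model only. Adjusted yield is computed per plot as observed
yield minus the phenology-expected value of the line; line-level adjusted
values average zero and are orthogonal to flowering by OLS construction.
Its heritability is computed by re-running the single-environment
decomposition on adjusted plot values.

The Fischer-Maurer susceptibility index is `DSI = [1 - Y_S/Y_F] / D_S` with
`D_S = (I_F - I_S)/I_F` from irrigation totals; crop-cycle totals
(360 vs 170 mm, `D_S = 0.528`) are the default, stress-window totals
(240 vs 50 mm) are exposed as an alternative. DSI is summarized by mean and
phenotypic CV over lines — no ANOVA applies, since it is built from line
means.

## Marker QC, imputation, LD (`marker_qc_ld`)

The filter cascade is fixed: monomorphic -> MAF -> marker missingness ->
sample missingness, then MAF is recomputed once and re-filtered (sample
removal can shift frequencies). Whether to recompute frequencies after
sample removal is a genuine free choice; the one-recheck rule keeps the
operation idempotent. Heterozygosity excess is screened with thresholds
mean + 3 SD (samples) and mean + 2 SD (markers), both computed before any
removal, samples first. Missing-rate presets {0.15, 0.20, 0.30} feed the
genomic-selection grid.

Imputation is categorical ({0,1,2}), seeded, and never alters observed
calls. Three methods: per-marker mode; k-nearest-neighbour majority vote
over samples (the pipeline default — on family-structured inbred genotypes
the nearest neighbours are family mates, which makes this both fast and
accurate); and an "rf-like" scheme (per-marker bagged classification
forests, 100 trees, on the 10 most-correlated markers) in the spirit of
iterative forest imputers. rf-like is the most accurate but costs minutes
at full panel size, so the drivers default to knn.

LD decay: pairwise squared Pearson correlation for all marker pairs within
a 50 kb window, per chromosome; a degree-2 polynomial fit, clipped to be
monotone non-increasing over the data range; summary = smallest distance at
which the clipped fit drops to half of the 90th percentile of pairwise r2.
The generator's coarse marker map produces a longer half-decay distance
than dense real GBS panels; the decay length is a qualitative, not a
quantitative, emulation target.

## Population structure (`structure_dpca`)

PCA of the centered dosage matrix (all components); k-means (10 restarts,
seeded) for K = 1..20 on the PC scores; `BIC(K) = n ln(WSS/n) + K ln(n)`
with the argmin (ties toward smaller K) selecting K. On the default
simulation K lands in the 14–18 bracket around the 16 true families. The
discriminant step fits an LDA of the cluster labels on a reduced PC basis
(min(50, n-K-1) components, keeping the problem well-posed); the number of
discriminant axes retained maximizes the a-score — observed reassignment
success minus its mean over 20 label-permuted replicates. Covariates for
GWAS/GS are the first min(7, retained) discriminant scores, column-
standardized.

## GWAS (`gwas_scan`)

A deliberately simple, fully documented scan replaces multi-locus
iterative methods: per SNP the fixed-effect model
`response ~ 1 + structure covariates + dosage`, a two-sided t test on the
dosage coefficient, computed for all SNPs at once by Frisch-Waugh
residualization. An optional kinship-GLS variant whitens by the Cholesky
factor of the REML-estimated `s2_g G + s2_e I`. Significance uses a
Bonferroni threshold (family-wise alpha 0.01 over the markers actually
tested); per-SNP explained variance is the incremental R2 over the
covariate-only model, in percent, summed into trait totals. Because each
hit's increment is over the covariates only (not over the other hits), the
trait total can exceed 100% when many mutually linked SNPs reach
significance; with the few near-independent hits typical of these traits it
reads as an additive decomposition. Genomic
inflation is summarized by lambda_GC; under permutation of the response it
sits in [0.8, 1.2]. On structured polygenic traits with few covariates the
unpermuted lambda exceeds 1 — expected behaviour for a single-marker scan,
not an error.

## Genomic prediction (`genomic_prediction`)

Four models predict line BLUPs from dosages:

* **rrBLUP** — `y = 1 mu + W q + (X b) + e`, `q ~ N(0, I s2_q)`; the ridge
  parameter `lambda = s2_e/s2_q` is estimated by exact REML profiled on the
  eigenbasis of `W W'`. Equivalence with VanRaden-GBLUP (below) at 1e-6 is
  the primary numerical oracle.
* **Bayesian Lasso** — double-exponential marker priors via the
  exponential-scale-mixture representation; scalar Gibbs updates with
  residual tracking (numba inner loop), inverse-Gaussian draws for the
  mixing scales, Gamma(0.1, 0.1) hyperprior on lambda^2, improper 1/sigma^2
  prior on the residual variance. Default chain 10,000 iterations / 1,000
  burn-in; reduced chains (2,000/200) are used in the smoke-scale runs.
  With sigma^2 and lambda^2 held fixed the single-predictor posterior mean
  matches 1-D numeric integration of the Laplace-prior posterior.
* **RKHS / GBLUP** — `y = 1 mu + g + e`, `var(g) = G s2_g` with
  `G = M M' / [2 sum p_i (1-p_i)]` (dosages centered at twice the observed
  allele frequency; zero-variance columns excluded; symmetrized and
  jittered to PSD). The Gibbs sampler works on the eigenbasis of G, where
  all genetic coordinates update independently; variance priors are
  scaled-inverse-chi-square (df 5) splitting var(y) 50/50 a priori.
  Unphenotyped lines are predicted through the kernel cross-block.
* **WGBLUP** — GBLUP with `G* = M D M' / [2 sum p_i (1-p_i)]`,
  `d_i = -log10(p_i)` from a GWAS on the *training partition only*,
  normalized to mean 1 and floored at 1e-3. A structural guard raises if
  supplied p-values declare provenance outside the training lines. The
  line-by-line weighted-kinship form resolves the ambiguity of defining a
  marker-weighted relationship matrix in a way that reduces exactly to
  GBLUP under uniform weights.

Cross-validation: seeded repeated 10-fold; predictive ability is the
Pearson correlation of predicted vs observed held-out responses, reported
per fold and summarized as mean/SD. The cross-environment protocol holds
out a fraction of the lines (10%), trains on the training environment's
BLUPs of the remainder, and validates against the other environment's BLUPs
of the held-out lines — a held-out-lines reading that avoids same-line
leakage; a same-line variant is deliberately not the default. All samplers
are bit-reproducible under fixed seeds.

## The synthetic generator (`synthetic_data`)

Genotypes: eight inbred parents receive homozygous alleles drawn per marker
from a Beta(0.5, 0.5) base frequency, independently per parent; each F5
line descends from one F1 of its cross through four selfing generations.
Meiosis places `1 + Poisson(0.5)` crossovers per chromosome (mean 1.5, one
obligate), uniformly in bp. Residual heterozygosity at F1-segregating loci
halves each generation to ~6.25% at F5 (the genome-wide mean marker
heterozygosity is that value scaled by the probability that a marker
segregates within a family, roughly 0.25–0.4 after MAF filtering). Markers
below the MAF floor are dropped; missingness is injected completely at
random (default 10%).

Phenotypes are built from standardized, in-sample orthogonalized marker
scores (planted QTL shares plus a 300-marker polygenic tail), so realized
breeding-value variances and correlations hit the configured targets
exactly and sampling noise enters only through block and plot errors. The
architecture: flowering has 7 QTLs (jointly ~55% of its genetic variance,
shared across environments, r_g = 1, stress mean shifted -2.8 d); stress
yield = escape_slope x flowering deviation + an independent
intrinsic-tolerance score scaled so total genetic variance meets its
target; favourable yield combines the flowering axis (genetic correlation
-0.5), the tolerance axis and an environment-specific score so that the
yield r_g target (0.84) holds exactly; straw biomass correlates 0.6 with
same-environment yield and 0.93 across environments. Default means, genetic
CVs and H2 values are the trial's reported ones (e.g. grain yield 0.88 /
2.28 t/ha, CV 28.7 / 35.1%, H2 0.70 / 0.69). Error variances follow from
H2 via `s2_e = n s2_g (1 - H2)/H2`; block variance is a quarter of the
error variance (plots within a managed container are relatively uniform).
Negative simulated yields are truncated at zero with a logged warning.

**What the generator does not emulate.** Real GBS panels (non-random
missingness, allele-frequency-dependent call quality), dominance and
epistasis, vernalization physiology, spatial field trends, and — most
importantly for genomic prediction — the real population's stronger
between-family differentiation. In the simulated population roughly half of
the genetic variance is within-family Mendelian sampling, which ~9 lines
per family cannot tag well; cross-validated predictive abilities therefore
sit near 0.35–0.55 rather than the 0.62–0.78 reported for the real trial.
Passing tests demonstrate correct estimators, calibrated nulls, correct
ordering properties (heritability monotonicity, cross-environment
attenuation) and exact recovery of the configured variance structure — not
that real-data predictive abilities are reproduced.

## Problem sizes used by the test suite and the acceptance script

The generator's scientific defaults (400 markers/chromosome, ~10k SNPs)
are kept for the analysis drivers; the test suite and the acceptance script
run the same code on a thinned marker map (80 markers/chromosome, ~2000
SNPs, the same 144 lines x 2 environments x 4 blocks) and reduced Gibbs
chains (2,000/200), sizes at which every property of interest is already
expressed. Monte-Carlo suites use 5–25 seeds depending on the variance of
the quantity under test.

## Known limitations

* The bootstrap SE of r_g uses moment-form components inside resamples;
  on strongly unbalanced data only the REML path is valid and the default
  estimators refuse unbalanced layouts outright.
* The a-score axis choice on weakly structured data can retain very few
  discriminant axes; covariate consumers fall back to "all retained".
* The rf-like imputer is a documented stand-in in the spirit of iterative
  forest imputation, not a re-implementation of any specific package.
* The single-marker GWAS is a transparent simplification of multi-locus
  mixed-model scans; on structured traits its unpermuted inflation factor
  exceeds 1 and hit lists should be read accordingly.
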