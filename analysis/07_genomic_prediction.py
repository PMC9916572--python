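"""Genomic prediction: the model grid (rrBLUP, Bayesian Lasso, RKHS/GBLUP,
WGBLUP; with and without structure covariates) under repeated 10-fold
cross-validation, and the cross-environment protocol for grain yield.

Usage: python analysis/07_genomic_prediction.py --vcf results/qc/genotypes_qc.vcf \
           --pheno results/sim/phenotypes.csv --scores results/structure/scores.csv \
           --repeats 2 --gibbs 2000 200 --seed 1 --out results/prediction
"""

import argparse
from pathlib import Path

import pandas as pd

from lupinqg import containers, pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--vcf", type=Path, default=Path("results/qc/genotypes_qc.vcf"))
    ap.add_argument("--pheno", type=Path, default=Path("results/sim/phenotypes.csv"))
    ap.add_argument("--scores", type=Path, default=Path("results/structure/scores.csv"))
    ap.add_argument("--folds", type=int, default=10)
    ap.add_argument("--repeats", type=int, default=2)
    ap.add_argument("--gibbs", type=int, nargs=2, default=(2000, 200),
                    metavar=("ITER", "BURN"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/prediction"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno = containers.read_vcf(args.vcf)
    plots = containers.read_pheno_csv(args.pheno)
    cov = pd.read_csv(args.scores, index_col=0).to_numpy()
    escape_out = pipeline.escape_analysis(plots)
    responses = pipeline.gwas_responses(plots, escape_out,
                                        list(geno.samples["id"]))

    grid = pipeline.prediction_grid(
        geno, responses, cov,
        traits=["grain_yield_stress", "grain_yield_favourable",
                "flowering_onset", "adjusted_yield"],
        folds=args.folds, repeats=args.repeats,
        gibbs=tuple(args.gibbs), seed=args.seed)
    grid.to_csv(args.out / "single_env_grid.csv", index=False)
    print(grid.round(3).to_string(index=False))

    ce = pipeline.cross_env_prediction(
        geno, responses, cov, repeats=args.repeats * 5,
        gibbs=tuple(args.gibbs), seed=args.seed)
    ce.to_csv(args.out / "cross_env.csv", index=False)
    print()
    print(ce.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
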