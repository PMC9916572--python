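"""Covariate-adjusted GWAS for grain yield in both environments, mean
flowering, and the phenology-adjusted yield, with Bonferroni control and
per-hit explained variance.

Usage: python analysis/06_gwas.py --vcf results/qc/genotypes_qc.vcf \
           --pheno results/sim/phenotypes.csv --scores results/structure/scores.csv \
           --alpha 0.01 --out results/gwas
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
    ap.add_argument("--alpha", type=float, default=0.01)
    ap.add_argument("--out", type=Path, default=Path("results/gwas"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno = containers.read_vcf(args.vcf)
    plots = containers.read_pheno_csv(args.pheno)
    cov = pd.read_csv(args.scores, index_col=0).to_numpy()
    escape_out = pipeline.escape_analysis(plots)
    responses = pipeline.gwas_responses(plots, escape_out,
                                        list(geno.samples["id"]))
    results = pipeline.gwas(geno, responses, cov, alpha=args.alpha)
    for name, res in results.items():
        scan = res["scan"]
        scan.table.to_csv(args.out / f"scan_{name}.csv", index=False)
        res["hits"].to_csv(args.out / f"hits_{name}.csv", index=False)
        print(f"{name}: m={scan.m_tested}, threshold={scan.threshold:.3e}, "
              f"hits={len(res['hits'])}, summed variance "
              f"{res['total_variance_pct']:.1f}%, lambda_GC={scan.lambda_gc:.2f}")


if __name__ == "__main__":
    main()
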