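"""Population structure: BIC-over-K curve from k-means on PC scores,
discriminant analysis of principal components at the selected K, and the
standardized structure covariates for GWAS / genomic prediction.

Usage: python analysis/05_structure.py --vcf results/qc/genotypes_qc.vcf \
           --kmax 20 --seed 1 --out results/structure
"""

import argparse
from pathlib import Path

import pandas as pd

from lupinqg import containers, pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--vcf", type=Path, default=Path("results/qc/genotypes_qc.vcf"))
    ap.add_argument("--kmax", type=int, default=20)
    ap.add_argument("--n-axes", type=int, default=7)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/structure"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno = containers.read_vcf(args.vcf)
    res, cov = pipeline.structure(geno, k_max=args.kmax, seed=args.seed,
                                  n_axes=args.n_axes)
    res.bic_curve.to_csv(args.out / "bic_curve.csv", index=False)
    pd.DataFrame({"line_id": geno.samples["id"],
                  "cluster": res.assignments}).to_csv(
        args.out / "assignments.csv", index=False)
    pd.DataFrame(cov, index=geno.samples["id"]).to_csv(args.out / "scores.csv")
    print(f"K selected: {res.K_selected}; retained discriminant axes: "
          f"{res.retained_axes}; covariates: {cov.shape[1]} columns")


if __name__ == "__main__":
    main()
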