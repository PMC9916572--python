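"""Multi-environment trial statistics: per-environment means, genetic CVs and
heritabilities, combined-analysis variance components and genetic
correlations tested against unity, plus line-mean trait correlations.

Usage: python analysis/02_met_statistics.py --pheno results/sim/phenotypes.csv \
           --out results/met
"""

import argparse
from pathlib import Path

from lupinqg import containers, phenotype_met, pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pheno", type=Path, default=Path("results/sim/phenotypes.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/met"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    plots = containers.read_pheno_csv(args.pheno)
    per_env, combined = pipeline.met_statistics(plots, seed=args.seed)
    per_env.to_csv(args.out / "per_environment.csv", index=False)
    combined.to_csv(args.out / "combined_gei.csv", index=False)
    print(per_env.round(3).to_string(index=False))
    print()
    print(combined.round(3).to_string(index=False))

    means = {}
    for trait in ("grain_yield", "straw_biomass", "flowering_onset"):
        for env in containers.ENVIRONMENTS:
            means[f"{trait}_{env}"] = containers.line_means(plots, trait, env)
    import pandas as pd
    lm = pd.DataFrame(means)
    r, p = phenotype_met.trait_correlations(lm)
    r.to_csv(args.out / "trait_correlations.csv")
    print("\nline-mean trait correlations written to trait_correlations.csv")


if __name__ == "__main__":
    main()
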