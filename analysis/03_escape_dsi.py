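"""Drought-escape regression of stress yield on flowering, phenology-adjusted
yield with its heritability, and the Fischer-Maurer drought susceptibility
index from irrigation totals.

Usage: python analysis/03_escape_dsi.py --pheno results/sim/phenotypes.csv \
           --if-mm 360 --is-mm 170 --out results/escape
"""

import argparse
from pathlib import Path

from lupinqg import containers, pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pheno", type=Path, default=Path("results/sim/phenotypes.csv"))
    ap.add_argument("--if-mm", type=float, default=360.0,
                    help="irrigation total, favourable regime (mm)")
    ap.add_argument("--is-mm", type=float, default=170.0,
                    help="irrigation total, stress regime (mm)")
    ap.add_argument("--out", type=Path, default=Path("results/escape"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    plots = containers.read_pheno_csv(args.pheno)
    out = pipeline.escape_analysis(
        plots, irrigation={"favourable": args.if_mm, "stress": args.is_mm})
    e = out["escape"]
    print(f"escape regression ({e.model_choice}): slope {e.slope:.4f} t/ha/day "
          f"(p={e.slope_p:.2g}), R2 {e.r2:.3f}")
    print(f"adjusted-yield H2: {out['adjusted_H2'].H2:.3f} "
          f"+- {out['adjusted_H2'].H2_se:.3f}")
    print(f"drought severity D_S = {out['D_S']:.3f}; "
          f"DSI mean {out['dsi_summary']['mean']:.3f}, "
          f"CV {out['dsi_summary']['cv_pct']:.1f}%")
    out["lines"].to_csv(args.out / "line_escape_dsi.csv")
    containers.write_json({
        "slope": e.slope, "intercept": e.intercept, "r2": e.r2,
        "model": e.model_choice, "D_S": out["D_S"],
        "dsi": out["dsi_summary"],
        "adjusted_H2": out["adjusted_H2"].H2,
    }, args.out / "escape_summary.json")


if __name__ == "__main__":
    main()
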