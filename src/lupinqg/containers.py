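"""Shared data containers and text-format I/O.

`GenotypeMatrix` holds biallelic SNP dosages (0/1/2, NaN = missing) for a set
of inbred lines together with marker map metadata.  Phenotypes travel as tidy
:class:`pandas.DataFrame` tables with one row per plot (line x environment x
block) — the same schema the field drivers read from CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical column order of the tidy plot-level phenotype table
PHENO_COLUMNS = [
    "line_id",
    "cross_id",
    "environment",
    "block",
    "grain_yield",
    "straw_biomass",
    "flowering_onset",
]

ENVIRONMENTS = ("stress", "favourable")


@dataclasses.dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with marker map metadata.

    Parameters
    ----------
    dosage
        float array (n_lines, n_markers); values in {0, 1, 2} or NaN for
        missing calls.
    markers
        DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based bp,
        strictly increasing within chromosome).
    samples
        DataFrame with columns ``id`` and optionally ``cross_id``.
    """

    dosage: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (lines x markers)")
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic summaries -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def marker_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=1)

    def marker_het_rate(self) -> np.ndarray:
        """Fraction of heterozygous calls among non-missing calls, per marker."""
        het = (self.dosage == 1).sum(axis=0)
        called = (~np.isnan(self.dosage)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, het / called, np.nan)

    def sample_het_rate(self) -> np.ndarray:
        het = (self.dosage == 1).sum(axis=1)
        called = (~np.isnan(self.dosage)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, het / called, np.nan)

    def subset(self, sample_mask=None, marker_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_lines, bool) if sample_mask is None else np.asarray(sample_mask)
        mm = np.ones(self.n_markers, bool) if marker_mask is None else np.asarray(marker_mask)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(sm, mm)].copy(),
            markers=self.markers.loc[mm].reset_index(drop=True),
            samples=self.samples.loc[sm].reset_index(drop=True),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage.copy(),
            self.markers.copy().reset_index(drop=True),
            self.samples.copy().reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased diploid GT calls as a plain-text VCF (missing = ./.)."""
    path = Path(path)
    chroms = list(dict.fromkeys(geno.markers["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lupinqg\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(geno.samples["id"].astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        dosage = geno.dosage
        for j, row in enumerate(geno.markers.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else _GT_CODE[int(d)] for d in dosage[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        rows.append(dos)
        meta.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS))
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos"])
    samples = pd.DataFrame({"id": sample_ids})
    return GenotypeMatrix(np.column_stack(rows) if rows else np.empty((len(sample_ids), 0)),
                          markers, samples)


# ---------------------------------------------------------------------------
# Phenotype table helpers
# ---------------------------------------------------------------------------


def add_derived_traits(plots: pd.DataFrame) -> pd.DataFrame:
    """Attach aerial biomass (grain + straw) and harvest index columns."""
    out = plots.copy()
    out["aerial_biomass"] = out["grain_yield"] + out["straw_biomass"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["harvest_index"] = out["grain_yield"] / out["aerial_biomass"]
    return out


def validate_plots(plots: pd.DataFrame) -> None:
    missing = [c for c in PHENO_COLUMNS if c not in plots.columns and c != "cross_id"]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    counts = plots.groupby(["line_id", "environment", "block"]).size()
    if (counts != 1).any():
        raise ValueError("phenotype table is not balanced: duplicated plots found")


def line_means(plots: pd.DataFrame, trait: str, environment: str | None = None) -> pd.Series:
    sub = plots if environment is None else plots[plots["environment"] == environment]
    return sub.groupby("line_id")[trait].mean()


def write_pheno_csv(plots: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in PHENO_COLUMNS if c in plots.columns]
    plots[cols].to_csv(path, index=False)


def read_pheno_csv(path: str | Path) -> pd.DataFrame:
    plots = pd.read_csv(path)
    validate_plots(plots)
    return plots


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
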