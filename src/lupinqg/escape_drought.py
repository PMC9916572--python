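"""Drought escape and susceptibility statistics.

Drought escape is quantified by regressing line-mean grain yield under stress
on the line-mean onset of flowering (averaged across environments, since
flowering shows no genotype-x-environment interaction).  The phenology-
adjusted ("intrinsic tolerance") yield of a plot is its observed yield minus
the yield expected from the line's flowering time under the fitted
regression; line-level adjusted values average zero by ordinary least
squares.  The Fischer-Maurer drought susceptibility index is

    DSI_i = [1 - Y_S,i / Y_F,i] / D_S,      D_S = (I_F - I_S) / I_F,

where Y_S, Y_F are line mean yields under stress and favourable conditions
and I_S, I_F the irrigation totals of the two regimes (crop-cycle totals by
default, 170 vs 360 mm).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import phenotype_met

#: crop-cycle irrigation totals (mm) of the favourable and stress regimes
IRRIGATION_CROP_CYCLE = {"favourable": 360.0, "stress": 170.0}
#: totals over the two-month stress-application window (mm)
IRRIGATION_STRESS_WINDOW = {"favourable": 240.0, "stress": 50.0}


@dataclasses.dataclass
class EscapeResult:
    """Escape regression fit.

    ``slope``/``intercept``/``r2`` always describe the *linear* fit (the
    escape slope in t/ha per day of delayed flowering); the quadratic term is
    diagnostic and, when significant at the retention level, defines the
    adjustment model instead.
    """

    slope: float                  # t/ha per day (linear fit)
    intercept: float              # t/ha (linear fit)
    r2: float                     # linear-fit R2
    slope_p: float
    slope_se: float
    quad_coef: float              # coefficient on centered flowering squared
    quad_p: float
    model_choice: str             # 'linear' or 'quadratic'
    line_flowering: pd.Series
    line_fitted: pd.Series        # expected yield per line (chosen model)
    line_adjusted: pd.Series      # residual = adjusted line yield (mean 0)
    _quad_params: tuple = (0.0, 0.0, 0.0)   # a, b, c in raw flowering units

    def predict(self, flowering: np.ndarray) -> np.ndarray:
        f = np.asarray(flowering, float)
        if self.model_choice == "quadratic":
            a, b, c = self._quad_params
            return a + b * f + c * f ** 2
        return self.intercept + self.slope * f


def fit_escape_regression(line_flowering: pd.Series, line_stress_yield: pd.Series,
                          quad_alpha: float = 0.05) -> EscapeResult:
    """OLS of line stress yield on line flowering; the quadratic term is
    retained for the adjustment model only when its coefficient is
    significant at ``quad_alpha``."""
    f = line_flowering.astype(float)
    y = line_stress_yield.astype(float).reindex(f.index)
    if len(f) < 3:
        raise ValueError("at least 3 lines required")
    if float(f.std()) == 0.0:
        raise ValueError("flowering is constant: no escape axis to regress on")
    if y.isna().any():
        raise ValueError("yield missing for some lines in the regression set")

    Xlin = sm.add_constant(f.to_numpy())
    lin = sm.OLS(y.to_numpy(), Xlin).fit()
    fc = f - f.mean()                       # centered to decorrelate the quadratic
    Xq = np.column_stack([np.ones(len(f)), fc, fc ** 2])
    quad = sm.OLS(y.to_numpy(), Xq).fit()
    quad_coef, quad_p = float(quad.params[2]), float(quad.pvalues[2])

    slope = float(lin.params[1])
    intercept = float(lin.params[0])
    # a degenerate (exact linear) fit makes the quadratic test meaningless
    lin_has_residual = float(lin.ssr) > 1e-12 * float(np.var(y.to_numpy())) * len(y)
    if lin_has_residual and np.isfinite(quad_p) and quad_p < quad_alpha:
        # express y = a + b f + c f^2 in raw flowering units
        c = quad_coef
        b = float(quad.params[1]) - 2 * c * f.mean()
        a = float(quad.params[0]) - float(quad.params[1]) * f.mean() + c * f.mean() ** 2
        fitted = a + b * f + c * f ** 2
        return EscapeResult(slope, intercept, float(lin.rsquared),
                            float(lin.pvalues[1]), float(lin.bse[1]),
                            quad_coef, quad_p, "quadratic",
                            f, fitted, y - fitted, (a, b, c))
    fitted = pd.Series(lin.fittedvalues, index=f.index)
    return EscapeResult(slope, intercept, float(lin.rsquared),
                        float(lin.pvalues[1]), float(lin.bse[1]),
                        quad_coef, quad_p, "linear",
                        f, fitted, y - fitted)


def adjusted_yield(plots_stress: pd.DataFrame, escape: EscapeResult,
                   trait: str = "grain_yield") -> tuple[pd.DataFrame, "phenotype_met.VarianceDecomposition"]:
    """Per-plot adjusted yield (observed minus phenology-expected) and its
    single-environment ANOVA/heritability.

    Returns the stress-environment plot table with an ``adjusted_yield``
    column, plus the variance decomposition of the adjusted values.
    """
    sub = plots_stress[plots_stress["environment"] == "stress"].copy()
    missing = set(sub["line_id"]) - set(escape.line_flowering.index)
    if missing:
        raise ValueError(f"lines absent from the escape regression: {sorted(missing)[:5]}")
    expected = escape.predict(
        escape.line_flowering.reindex(sub["line_id"]).to_numpy())
    sub["adjusted_yield"] = sub[trait].to_numpy() - expected
    decomp = phenotype_met.fit_single_env(sub, "adjusted_yield", "stress")
    return sub, decomp


def drought_severity(I_F: float, I_S: float) -> float:
    """Drought-severity index D_S = (I_F - I_S) / I_F."""
    if I_F <= 0:
        raise ValueError("favourable irrigation total must be positive")
    if I_S > I_F:
        raise ValueError("I_S > I_F is not a stress contrast")
    return (I_F - I_S) / I_F


def dsi(Y_S: pd.Series, Y_F: pd.Series, D_S: float) -> tuple[pd.Series, dict]:
    """Per-line Fischer-Maurer drought susceptibility index and its summary.

    Lines with zero favourable yield are excluded with a flag; the summary is
    the mean and the phenotypic CV over lines (no ANOVA applies, since DSI is
    built from line means).
    """
    if not 0.0 < D_S <= 1.0:
        raise ValueError("D_S must be in (0, 1]")
    Y_F = Y_F.reindex(Y_S.index)
    valid = Y_F > 0
    vals = (1.0 - Y_S[valid] / Y_F[valid]) / D_S
    vals.name = "dsi"
    summary = {
        "mean": float(vals.mean()),
        "cv_pct": float(100.0 * vals.std(ddof=1) / vals.mean()) if vals.mean() != 0 else np.nan,
        "n_excluded_zero_YF": int((~valid).sum()),
    }
    return vals, summary
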