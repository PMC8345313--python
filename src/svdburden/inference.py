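"""Auxiliary inference: dependent-correlation comparison, FDR, residualization.

The Williams test compares two correlations r12 and r13 that share variable
1 (here: one outcome correlated with two competing predictors measured on
the same people).  Benjamini-Hochberg step-up adjustment controls the false
discovery rate within a declared family of tests.  Residualization removes
the linear effect of the scan-test interval from manifest cognitive scores
before any latent modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests


@dataclass
class WilliamsResult:
    t_value: float
    df: int
    p_one_sided: float
    p_two_sided: float
    r12: float
    r13: float
    r23: float
    n: int


def williams_test(r12: float, r13: float, r23: float, n: int) -> WilliamsResult:
    """Williams' t (df = n - 3) for H0: rho12 = rho13 with shared variable 1.

    t = (r12 - r13) * sqrt[ (n-1)(1+r23) /
          ( 2 |R| (n-1)/(n-3) + rbar^2 (1-r23)^3 ) ]

    where |R| is the determinant of the 3x3 correlation matrix and
    rbar = (r12 + r13)/2.  The one-sided p is taken in the direction of the
    observed difference; both tails are always reported.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} outside (-1, 1)")
    if n < 4:
        raise ValueError("n must be at least 4")
    detR = 1 - r12 ** 2 - r13 ** 2 - r23 ** 2 + 2 * r12 * r13 * r23
    if detR <= 0:
        raise ValueError("correlation triple is not positive definite")
    rbar = 0.5 * (r12 + r13)
    df = n - 3
    denom = 2 * detR * (n - 1) / df + rbar ** 2 * (1 - r23) ** 3
    t_val = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    p_two = 2 * t_dist.sf(abs(t_val), df)
    p_one = t_dist.sf(abs(t_val), df)
    return WilliamsResult(float(t_val), df, float(p_one), float(min(p_two, 1.0)),
                          r12, r13, r23, n)


@dataclass
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    family_label: str


def bh_adjust(pvals, family_label: str = "") -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return AdjustedPValues(p, p.copy(), family_label)
    ok = ~np.isnan(p)
    adj = np.full(p.shape, np.nan)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return AdjustedPValues(p, adj, family_label)


def residualize_for_interval(table, cognitive_columns: list[str],
                             interval_column: str):
    """Replace each cognitive column by residuals of its regression on the
    scan-test interval (days), computed over complete pairs.

    Missing cells stay missing.  A constant interval column degenerates the
    regression to mean-centering (logged implicitly by the zero slope).
    Returns an object of the same type as the input (CohortTable passthrough).
    """
    is_cohort = hasattr(table, "df")
    df = (table.df if is_cohort else table).copy()
    iv = df[interval_column].to_numpy(dtype=float)
    for col in cognitive_columns:
        y = df[col].to_numpy(dtype=float)
        m = ~(np.isnan(y) | np.isnan(iv))
        if m.sum() < 3:
            raise ValueError(f"{col}: fewer than 3 complete pairs with interval")
        x = iv[m]
        yy = y[m]
        vx = x.var()
        slope = 0.0 if vx == 0 else np.cov(x, yy, bias=True)[0, 1] / vx
        intercept = yy.mean() - slope * x.mean()
        resid = np.where(np.isnan(y) | np.isnan(iv), np.nan,
                         y - (intercept + slope * iv))
        df[col] = resid
    if is_cohort:
        out = table.replace_df(df)
        return out
    return df
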