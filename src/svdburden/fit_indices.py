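"""Absolute fit assessment: RMSEA, CFI, TLI, SRMR and acceptability verdicts.

All four indices are computed from the mean-and-variance adjusted chi-square
(the reporting convention that goes with the DWLS/WLSMV estimator), with the
independence (zero-correlation) model as the CFI/TLI baseline.  Acceptability
thresholds: RMSEA < 0.06, CFI > 0.95, TLI > 0.95, SRMR < 0.08.  TLI is
deliberately left unclamped and can exceed 1 in well-fitting models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlations import MixedCorrelationMatrix

THRESHOLDS = {"rmsea": 0.06, "cfi": 0.95, "tli": 0.95, "srmr": 0.08}


@dataclass
class BaselineResult:
    """Chi-square of the independence model (all correlations fixed to 0)."""
    chisq_adjusted: float
    df_adjusted: float
    chisq_unadjusted: float
    df: int


@dataclass
class FitIndices:
    rmsea: float
    cfi: float
    tli: float
    srmr: float
    verdicts: dict[str, bool]
    baseline: BaselineResult
    saturated: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"rmsea": self.rmsea, "cfi": self.cfi, "tli": self.tli,
                "srmr": self.srmr}


def baseline_model(moments: MixedCorrelationMatrix) -> BaselineResult:
    """Independence model: every correlation fixed to zero, thresholds free.

    With no free correlation parameters the DWLS discrepancy is computed
    directly and adjusted with U = W (no projection).
    """
    tri = np.triu_indices(moments.p, k=1)
    s = moments.estimates[tri]
    w = np.maximum(moments.asymptotic_variances[tri], 1e-12)
    F = float(np.sum(s ** 2 / w))
    df = len(s)
    gamma = moments.gamma
    if gamma is None:
        gamma = np.diag(w)
    M = gamma / w[:, None]          # diag(1/w) @ gamma
    tr1 = float(np.trace(M))
    tr2 = float(np.trace(M @ M))
    if df == 0 or tr2 <= 0:
        return BaselineResult(0.0, 0.0, F, df)
    return BaselineResult(F * tr1 / tr2, tr1 ** 2 / tr2, F, df)


def srmr(residuals: np.ndarray) -> float:
    """Root mean square of the residual correlations (unique off-diagonals).

    Thresholds are estimated saturated in the first stage, so their
    residuals are identically zero and contribute nothing.
    """
    if residuals.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(residuals ** 2)))


def fit_indices(fit, baseline: BaselineResult, n: int,
                rmsea_denominator: str = "n-1") -> FitIndices:
    """RMSEA/CFI/TLI/SRMR from a FitResult and its baseline.

    rmsea_denominator: ``"n-1"`` (default) or ``"n"``; software conventions
    differ and the choice only matters in small samples.
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    chisq, df = fit.chisq_adjusted, fit.df_adjusted
    chisq_b, df_b = baseline.chisq_adjusted, baseline.df_adjusted
    s = srmr(fit.residuals)
    if fit.df == 0:
        out = FitIndices(0.0, 1.0, 1.0, s, {}, baseline, saturated=True)
    else:
        denom = (n - 1) if rmsea_denominator == "n-1" else n
        rmsea = float(np.sqrt(max(0.0, (chisq - df) / (df * denom))))
        num = max(chisq - df, 0.0)
        den = max(chisq_b - df_b, chisq - df, 0.0)
        cfi = 1.0 - num / den if den > 0 else 1.0
        if df_b > 0 and df > 0 and (chisq_b / df_b) != 1.0:
            tli = ((chisq_b / df_b) - (chisq / df)) / ((chisq_b / df_b) - 1.0)
        else:
            tli = 1.0
        cfi = float(np.clip(cfi, 0.0, 1.0))
        out = FitIndices(rmsea, cfi, float(tli), s, {}, baseline)
    out.verdicts = {
        "rmsea": out.rmsea < THRESHOLDS["rmsea"],
        "cfi": out.cfi > THRESHOLDS["cfi"],
        "tli": out.tli > THRESHOLDS["tli"],
        "srmr": out.srmr < THRESHOLDS["srmr"],
    }
    return out
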