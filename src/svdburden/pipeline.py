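"""Orchestration of the full SVD-burden / cognition analysis.

Reproduces the published analysis plan end to end on any cohort table with
the expected columns (real or simulated): measurement models for the
computational SVD latent, the ordinal visual-rating (Staals-style) SVD
latent and the vascular-risk covariate factor; stepwise covariate-adjusted
latent regressions for three predictors x four cognitive outcomes; an
orthogonal bifactor model with simultaneous covariates; Williams tests
comparing dependent predictor-outcome correlations; and FDR adjustment.
Results are emitted as a report shaped like the published tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import sem
from .cohort import (
    COGNITIVE_TESTS,
    COVARIATES,
    DOMAINS,
    REVERSED_COLUMNS,
    STAALS_INDICATORS,
    SVD_MARKERS,
    VASCULAR_INDICATORS,
    CohortTable,
)
from .correlations import (
    CONTINUOUS,
    MixedCorrelationMatrix,
    VariableDef,
    VariableSchema,
    mixed_matrix,
)
from .fit_indices import FitIndices, baseline_model, fit_indices
from .inference import bh_adjust, residualize_for_interval, williams_test

logger = logging.getLogger("svdburden")

PREDICTORS = ("svd_latent", "wmh_tiv", "staals_latent")
OUTCOMES = ("g", "speed", "memory", "visuospatial")

#: covariate columns in the canonical (published) entry order
COVARIATE_ORDER = ["age", "sex", "vascular_risk_score", "hads_depression",
                   "age11_iq"]
STEP_LABELS = ["none", "+ age", "+ age + sex", "+ age + sex + vascular risk",
               "+ age + sex + vascular risk + depression",
               "+ age + sex + vascular risk + depression + age-11 IQ"]

OUTCOME_INDICATORS = {
    "g": COGNITIVE_TESTS,
    "speed": DOMAINS["speed"],
    "memory": DOMAINS["memory"],
    "visuospatial": DOMAINS["visuospatial"],
}


@dataclass
class StudyConfig:
    """Knobs for a full study run; defaults mirror the published analysis."""
    identification: str = sem.UNIT_VARIANCE
    rmsea_denominator: str = "n-1"
    fdr_family: str = "per_table"        # per_table | global
    covariate_order: list[str] = field(default_factory=lambda:
                                       list(COVARIATE_ORDER))
    bifactor_covariates_on_all: bool = True   # else: covariates -> g only
    min_pair_n: int = 10

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class AnalysisReport:
    """Table-shaped results grid plus comparisons and the bifactor block."""
    rows: pd.DataFrame
    measurement: pd.DataFrame
    bifactor: pd.DataFrame
    bifactor_fit: dict
    comparisons: pd.DataFrame

    def to_csv(self, out_dir: str) -> None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        self.rows.to_csv(f"{out_dir}/stepwise_models.csv", index=False)
        self.measurement.to_csv(f"{out_dir}/measurement_models.csv", index=False)
        self.bifactor.to_csv(f"{out_dir}/bifactor_paths.csv", index=False)
        self.comparisons.to_csv(f"{out_dir}/williams_comparisons.csv", index=False)
        with open(f"{out_dir}/results.json", "w") as fh:
            json.dump({
                "stepwise": self.rows.to_dict(orient="records"),
                "measurement": self.measurement.to_dict(orient="records"),
                "bifactor": self.bifactor.to_dict(orient="records"),
                "bifactor_fit": self.bifactor_fit,
                "comparisons": self.comparisons.to_dict(orient="records"),
            }, fh, indent=1, default=str)

    def render_markdown(self) -> str:
        def fmt_p(p):
            if isinstance(p, float) and np.isfinite(p):
                return "<0.001" if p < 0.001 else f"{p:.3f}"
            return ""
        lines = ["# Stepwise latent regressions", ""]
        cols = ["predictor", "outcome", "step_label", "beta", "se", "ci_low",
                "ci_high", "p_raw", "p_fdr", "rmsea", "cfi", "tli", "srmr"]
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for _, r in self.rows.iterrows():
            vals = []
            for c in cols:
                v = r[c]
                if c in ("p_raw", "p_fdr"):
                    vals.append(fmt_p(v))
                elif isinstance(v, float):
                    vals.append(f"{v:.3f}")
                else:
                    vals.append(str(v))
            lines.append("| " + " | ".join(vals) + " |")
        lines += ["", "# Bifactor paths", ""]
        for _, r in self.bifactor.iterrows():
            lines.append(
                f"- SVD -> {r['outcome']}: {r['beta']:.3f} "
                f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}], "
                f"p(FDR) = {fmt_p(r['p_fdr'])}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def prepare_analysis_table(table: CohortTable,
                           config: StudyConfig | None = None) -> CohortTable:
    """Pre-model preparation mirroring the published pipeline.

    Reversed-scale test scores are sign-flipped so higher = better; manifest
    cognitive scores are residualized for the scan-test interval; WMH/TIV is
    z-scored into an observed predictor column (its raw scale, mean ~0.008,
    would ill-condition the optimizer); the vascular-risk factor score is
    appended as a covariate column.
    """
    config = config or StudyConfig()
    df = table.df.copy()
    for col in REVERSED_COLUMNS:
        if col in df.columns:
            df[col] = -df[col]
    work = table.replace_df(df)
    work = residualize_for_interval(
        work, [t for t in COGNITIVE_TESTS if t in df.columns],
        "scan_interval_days")
    df = work.df
    x = df["wmh_tiv"].to_numpy(dtype=float)
    df["wmh_tiv_z"] = (x - np.nanmean(x)) / np.nanstd(x)
    defs = list(table.schema) + [
        VariableDef("wmh_tiv_z", CONTINUOUS, role="covariate")]
    out = CohortTable(df, VariableSchema(defs), dict(table.provenance))
    scores, _, _ = build_vascular_risk_factor(out, config)
    df["vascular_risk_score"] = scores.to_numpy()
    defs.append(VariableDef("vascular_risk_score", CONTINUOUS, role="covariate"))
    return CohortTable(df, VariableSchema(defs), dict(table.provenance))


# ---------------------------------------------------------------------------
# measurement models
# ---------------------------------------------------------------------------

def _fit_and_assess(spec, moments, n, config):
    fit = sem.fit_dwls(spec, moments)
    std = sem.standardize(fit)
    base = baseline_model(fit.moments)
    idx = fit_indices(fit, base, n, config.rmsea_denominator)
    return fit, std, idx


def build_svd_measurement_model(table: CohortTable,
                                config: StudyConfig | None = None,
                                moments: MixedCorrelationMatrix | None = None):
    """One-factor CFA of the four computational SVD markers.

    WMH/TIV and PVS count are continuous; lacunes and microbleeds are binary
    (probit).  Returns (FitResult, StandardizedSolution, FitIndices).
    """
    config = config or StudyConfig()
    spec = sem.ModelSpec(factors={"svd": list(SVD_MARKERS)},
                         identification=config.identification)
    if moments is None:
        moments = mixed_matrix(table, table.schema, spec.indicator_order,
                               config.min_pair_n)
    return _fit_and_assess(spec, moments, table.n_rows, config)


def build_staals_measurement_model(table: CohortTable,
                                   config: StudyConfig | None = None,
                                   moments: MixedCorrelationMatrix | None = None):
    """One-factor CFA of the five visual-rating SVD indicators.

    Two Fazekas scales (0-3) and the basal-ganglia PVS rating (0-4) are
    ordinal; lacunes and microbleeds binary; all via polychorics.
    """
    config = config or StudyConfig()
    spec = sem.ModelSpec(factors={"svd_ratings": list(STAALS_INDICATORS)},
                         identification=config.identification)
    if moments is None:
        moments = mixed_matrix(table, table.schema, spec.indicator_order,
                               config.min_pair_n)
    return _fit_and_assess(spec, moments, table.n_rows, config)


def build_vascular_risk_factor(table: CohortTable,
                               config: StudyConfig | None = None):
    """Vascular-risk CFA (3 binary + 4 continuous indicators) and its
    regression-method factor scores, standardized over scored rows."""
    config = config or StudyConfig()
    spec = sem.ModelSpec(factors={"vascular_risk": list(VASCULAR_INDICATORS)},
                         identification=config.identification)
    moments = mixed_matrix(table, table.schema, spec.indicator_order,
                           config.min_pair_n)
    fit = sem.fit_dwls(spec, moments)
    std = sem.standardize(fit)
    scores = sem.factor_scores(fit, table, "vascular_risk")
    return scores, fit, std


# ---------------------------------------------------------------------------
# stepwise structural models
# ---------------------------------------------------------------------------

def _structural_spec(predictor: str, outcome: str, covariates: list[str],
                     identification: str) -> sem.ModelSpec:
    factors = {outcome: list(OUTCOME_INDICATORS[outcome])}
    observed = list(covariates)
    if predictor == "svd_latent":
        factors["svd"] = list(SVD_MARKERS)
        pred_name = "svd"
    elif predictor == "staals_latent":
        factors["svd_ratings"] = list(STAALS_INDICATORS)
        pred_name = "svd_ratings"
    elif predictor == "wmh_tiv":
        observed = ["wmh_tiv_z"] + observed
        pred_name = "wmh_tiv_z"
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    return sem.ModelSpec(
        factors=factors,
        regressions={outcome: [pred_name] + list(covariates)},
        observed_exogenous=observed,
        identification=identification)


def run_stepwise_models(table: CohortTable, predictor: str, outcome: str,
                        config: StudyConfig | None = None,
                        moments: MixedCorrelationMatrix | None = None) -> list[dict]:
    """Six nested covariate steps for one predictor-outcome pair.

    Covariates correlate freely with one another and with the predictor and
    regress onto the cognitive factor.  Returns one result row per step;
    non-converged fits carry flags instead of aborting the grid.
    """
    config = config or StudyConfig()
    rows = []
    for step in range(6):
        covs = config.covariate_order[:step]
        spec = _structural_spec(predictor, outcome, covs,
                                config.identification)
        vars_needed = spec.indicator_order
        mom = (moments.submatrix(vars_needed) if moments is not None
               else mixed_matrix(table, table.schema, vars_needed,
                                 config.min_pair_n))
        row = {"predictor": predictor, "outcome": outcome, "step": step,
               "step_label": STEP_LABELS[step]}
        try:
            fit, std, idx = _fit_and_assess(spec, mom, table.n_rows, config)
            path = std.paths[(std.paths["outcome"] == outcome)
                             & (std.paths["predictor"].isin(
                                 ("svd", "svd_ratings", "wmh_tiv_z")))].iloc[0]
            row.update(beta=float(path["est"]), se=float(path["se"]),
                       ci_low=float(path["ci_low"]),
                       ci_high=float(path["ci_high"]),
                       p_raw=float(path["p"]),
                       rmsea=idx.rmsea, cfi=idx.cfi, tli=idx.tli,
                       srmr=idx.srmr,
                       r2_outcome=float(std.r2_latent[outcome]),
                       variance_explained=float(path["est"]) ** 2,
                       flags=";".join(std.flags))
        except Exception as exc:    # keep the grid alive; flag the row
            logger.warning("stepwise fit failed (%s, %s, step %d): %s",
                           predictor, outcome, step, exc)
            row.update(beta=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_raw=np.nan, rmsea=np.nan, cfi=np.nan, tli=np.nan,
                       srmr=np.nan, r2_outcome=np.nan,
                       variance_explained=np.nan, flags=f"error:{exc}")
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# bifactor model
# ---------------------------------------------------------------------------

def bifactor_spec(covariates: list[str], identification: str,
                  covariates_on_all: bool = True) -> sem.ModelSpec:
    """Orthogonal bifactor cognitive model with latent SVD as predictor.

    Every test loads on g and on its domain factor; g and the domain factors
    are endogenous (regressed on SVD and the covariates) with mutually
    orthogonal disturbances — the bifactor constraint.
    """
    factors = {"svd": list(SVD_MARKERS), "g": list(COGNITIVE_TESTS)}
    factors.update({d: list(t) for d, t in DOMAINS.items()})
    preds = ["svd"] + list(covariates)
    regressions = {"g": list(preds)}
    for d in DOMAINS:
        regressions[d] = list(preds) if covariates_on_all else ["svd"]
    return sem.ModelSpec(factors=factors, regressions=regressions,
                         observed_exogenous=list(covariates),
                         identification=identification)


def run_bifactor_model(table: CohortTable, config: StudyConfig | None = None,
                       moments: MixedCorrelationMatrix | None = None):
    """Fit the bifactor SEM with simultaneous covariates; FDR across the
    four SVD paths.  Returns (block DataFrame, FitIndices, FitResult)."""
    config = config or StudyConfig()
    covs = [c for c in config.covariate_order if c in table.df.columns]
    spec = bifactor_spec(covs, config.identification,
                         config.bifactor_covariates_on_all)
    if moments is None:
        moments = mixed_matrix(table, table.schema, spec.indicator_order,
                               config.min_pair_n)
    fit, std, idx = _fit_and_assess(spec, moments, table.n_rows, config)
    if not fit.converged:
        logger.warning("bifactor model did not converge (gradient %.2e)",
                       fit.gradient_norm)
    rows = []
    for outcome in ("g", "speed", "memory", "visuospatial"):
        path = std.paths[(std.paths["outcome"] == outcome)
                         & (std.paths["predictor"] == "svd")].iloc[0]
        rows.append({"outcome": outcome, "beta": float(path["est"]),
                     "se": float(path["se"]),
                     "ci_low": float(path["ci_low"]),
                     "ci_high": float(path["ci_high"]),
                     "p_raw": float(path["p"]),
                     "r2_outcome": float(std.r2_latent[outcome]),
                     "flags": ";".join(std.flags)})
    block = pd.DataFrame(rows)
    block["p_fdr"] = bh_adjust(block["p_raw"], "bifactor").adjusted
    return block, idx, fit


# ---------------------------------------------------------------------------
# predictor comparison (Williams tests on factor-score correlations)
# ---------------------------------------------------------------------------

def _predictor_scores(table, predictor, config) -> pd.Series:
    if predictor == "wmh_tiv":
        x = table.df["wmh_tiv_z"]
        return (x - x.mean()) / x.std()
    which = {"svd_latent": build_svd_measurement_model,
             "staals_latent": build_staals_measurement_model}[predictor]
    fit, _, _ = which(table, config)
    return sem.factor_scores(fit, table, list(fit.spec.factors)[0])


def _outcome_scores(table, outcome, config) -> pd.Series:
    spec = sem.ModelSpec(factors={outcome: list(OUTCOME_INDICATORS[outcome])},
                         identification=config.identification)
    mom = mixed_matrix(table, table.schema, spec.indicator_order,
                       config.min_pair_n)
    fit = sem.fit_dwls(spec, mom)
    return sem.factor_scores(fit, table, outcome)


def compare_predictors(table: CohortTable, predictor_a: str, predictor_b: str,
                       config: StudyConfig | None = None) -> pd.DataFrame:
    """Williams one-sided t per outcome for two competing predictors.

    Latent predictors and outcomes enter through regression-method factor
    scores; WMH/TIV enters as the observed standardized column.  The t is
    signed as r(outcome, A) - r(outcome, B): with negative predictor-outcome
    correlations, a stronger A association gives a negative t.
    """
    config = config or StudyConfig()
    sa = _predictor_scores(table, predictor_a, config)
    sb = _predictor_scores(table, predictor_b, config)
    rows = []
    for outcome in OUTCOMES:
        so = _outcome_scores(table, outcome, config)
        m = ~(sa.isna() | sb.isna() | so.isna())
        n = int(m.sum())
        r12 = float(np.corrcoef(so[m], sa[m])[0, 1])
        r13 = float(np.corrcoef(so[m], sb[m])[0, 1])
        r23 = float(np.corrcoef(sa[m], sb[m])[0, 1])
        res = williams_test(r12, r13, r23, n)
        rows.append({"outcome": outcome, "predictor_a": predictor_a,
                     "predictor_b": predictor_b, "r_outcome_a": r12,
                     "r_outcome_b": r13, "r_a_b": r23, "n": n,
                     "t": res.t_value, "df": res.df,
                     "p_one_sided": res.p_one_sided,
                     "p_two_sided": res.p_two_sided})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def run_full_study(table: CohortTable,
                   config: StudyConfig | None = None) -> AnalysisReport:
    """The complete analysis grid on a prepared or raw cohort table.

    Emits 3 predictors x 4 outcomes x 6 covariate steps = 72 stepwise rows,
    two measurement-model rows, the bifactor block, and Williams comparisons
    (computational SVD latent vs WMH/TIV and vs the visual-rating latent).
    """
    config = config or StudyConfig()
    if "vascular_risk_score" not in table.df.columns:
        table = prepare_analysis_table(table, config)

    all_vars = (SVD_MARKERS + STAALS_INDICATORS + COGNITIVE_TESTS
                + ["wmh_tiv_z"] + config.covariate_order)
    all_vars = [v for v in dict.fromkeys(all_vars) if v in table.df.columns]
    logger.info("estimating global mixed correlation matrix (%d variables)",
                len(all_vars))
    moments = mixed_matrix(table, table.schema, all_vars, config.min_pair_n)

    meas_rows = []
    for which, builder in (("svd", build_svd_measurement_model),
                           ("staals", build_staals_measurement_model)):
        fit, std, idx = builder(table, config,
                                moments.submatrix(fit_vars(which)))
        lam = {r["indicator"]: r["est"] for _, r in std.loadings.iterrows()}
        meas_rows.append({"model": which, **idx.as_dict(),
                          "chisq_adjusted": fit.chisq_adjusted,
                          "df_adjusted": fit.df_adjusted,
                          "loadings": json.dumps({k: round(v, 4)
                                                  for k, v in lam.items()}),
                          "communalities": json.dumps(
                              {k: round(std.r2_indicator[k], 4)
                               for k in fit.variables}),
                          "flags": ";".join(std.flags)})

    rows = []
    for predictor in PREDICTORS:
        for outcome in OUTCOMES:
            rows.extend(run_stepwise_models(table, predictor, outcome,
                                            config, moments))
    rows = pd.DataFrame(rows)
    if config.fdr_family == "global":
        rows["p_fdr"] = bh_adjust(rows["p_raw"], "global").adjusted
    else:
        rows["p_fdr"] = np.nan
        for predictor in PREDICTORS:
            m = rows["predictor"] == predictor
            rows.loc[m, "p_fdr"] = bh_adjust(rows.loc[m, "p_raw"],
                                             predictor).adjusted

    bif_block, bif_idx, _ = run_bifactor_model(table, config, moments)
    comparisons = pd.concat([
        compare_predictors(table, "svd_latent", "wmh_tiv", config),
        compare_predictors(table, "svd_latent", "staals_latent", config),
    ], ignore_index=True)

    return AnalysisReport(rows=rows, measurement=pd.DataFrame(meas_rows),
                          bifactor=bif_block,
                          bifactor_fit=bif_idx.as_dict(),
                          comparisons=comparisons)


def fit_vars(which: str) -> list[str]:
    return list(SVD_MARKERS) if which == "svd" else list(STAALS_INDICATORS)
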