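"""DWLS structural-equation engine: implied moments, fitting oracles,
standardization, and factor scores."""

import numpy as np
import pandas as pd
import pytest

import svdburden as sv
from svdburden import sem
from svdburden.correlations import MixedCorrelationMatrix, mixed_matrix
from svdburden.sem import ModelSpec, ModelSpecError, ParameterVector


def moments_from_matrix(names, R, n=1000, avar=None):
    """Wrap a plain correlation matrix as moment input with uniform weights."""
    p = len(names)
    if avar is None:
        avar = 1.0 / n
    n_mom = p * (p - 1) // 2
    return MixedCorrelationMatrix(
        list(names), np.asarray(R, float), {}, {}, np.full((p, p), n),
        np.full((p, p), avar), np.diag(np.full(n_mom, avar)))


def one_factor_pop(lams):
    lams = np.asarray(lams, float)
    R = np.outer(lams, lams)
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

def test_spec_rejects_cyclic_regressions():
    with pytest.raises(ModelSpecError, match="cycle"):
        ModelSpec(factors={"a": ["x1", "x2"], "b": ["y1", "y2"]},
                  regressions={"a": ["b"], "b": ["a"]})


def test_spec_rejects_unknown_predictor_and_empty_factor():
    with pytest.raises(ModelSpecError, match="unknown predictor"):
        ModelSpec(factors={"a": ["x1"]}, regressions={"a": ["ghost"]})
    with pytest.raises(ModelSpecError, match="no indicators"):
        ModelSpec(factors={"a": []})


def test_spec_yaml_round_trip():
    spec = ModelSpec(factors={"f": ["a", "b", "c"]},
                     regressions={"f": ["z"]},
                     observed_exogenous=["z"],
                     covariances={("f", "z"): 0.0},
                     identification=sem.FIRST_LOADING)
    back = ModelSpec.from_yaml(spec.to_yaml())
    assert back.factors == spec.factors
    assert back.regressions == spec.regressions
    assert back.covariances == spec.covariances
    assert back.identification == spec.identification


def test_parameter_vector_round_trips_through_index_map():
    spec = ModelSpec(factors={"f": ["a", "b", "c"]})
    pm = ParameterVector(spec)
    theta = np.array([0.3, -0.2, 0.9])
    pm.set_free(theta)
    assert np.allclose(pm.free_values(), theta)
    Lam, B, Psi = pm.matrices()
    assert np.allclose(Lam[:, 0], theta)
    assert Psi[0, 0] == 1.0


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def test_implied_moments_zero_loadings_identity():
    spec = ModelSpec(factors={"f": ["a", "b", "c"]})
    pm = ParameterVector(spec)
    pm.set_free(np.zeros(3))
    assert np.allclose(sem.implied_moments(spec, pm), np.eye(3))


def test_implied_moments_hand_products():
    spec = ModelSpec(factors={"f": ["a", "b", "c"]})
    pm = ParameterVector(spec)
    pm.set_free(np.array([0.5, 0.6, 0.7]))
    S = sem.implied_moments(spec, pm)
    assert S[0, 1] == pytest.approx(0.30)
    assert S[0, 2] == pytest.approx(0.35)
    assert S[1, 2] == pytest.approx(0.42)
    assert np.allclose(np.diag(S), 1.0)


def test_implied_moments_match_generator_population(defaults):
    """The generator's population matrix and the engine's sigma(theta) are
    the same algebra evaluated at the generating truth."""
    names, S_pop = defaults.population_correlations()
    spec = ModelSpec(
        factors={"svd": sv.SVD_MARKERS, "g": sv.COGNITIVE_TESTS,
                 **{d: list(t) for d, t in sv.DOMAINS.items()},
                 "vascular_risk": sv.VASCULAR_INDICATORS},
        regressions={o: list(sv.cohort.EXOGENOUS_LATENTS)
                     if o == "g" else ["svd"]
                     for o in ("g", "speed", "memory", "visuospatial")},
        observed_exogenous=list(sv.COVARIATES))
    pm = ParameterVector(spec)
    exo = sv.cohort.EXOGENOUS_LATENTS
    R_exo = defaults.covariate_correlations.loc[exo, exo].to_numpy()
    for e in pm.entries:
        if e.kind == "lam":
            if e.a == "svd":
                e.value = defaults.svd_loadings[e.b]
            elif e.a == "g":
                e.value = defaults.cognitive_loadings_g[e.b]
            elif e.a in sv.DOMAINS:
                e.value = defaults.cognitive_loadings_domain[e.b][1]
            elif e.a == "vascular_risk":
                e.value = defaults.vascular_loadings[e.b]
        elif e.kind == "beta":
            e.value = defaults.structural_paths.get((e.a, e.b), 0.0)
        elif e.kind == "psi":
            if e.a == e.b and e.a in sv.cohort.ENDOGENOUS_LATENTS:
                b = np.array([defaults.structural_paths.get((e.a, x), 0.0)
                              for x in exo])
                e.value = 1.0 - float(b @ R_exo @ b)
            elif e.a != e.b and e.a in exo and e.b in exo:
                e.value = defaults.covariate_correlations.loc[e.a, e.b]
    S = sem.implied_moments(spec, pm)
    order = spec.indicator_order
    idx = [names.index(v) for v in order]
    assert np.allclose(S, S_pop[np.ix_(idx, idx)], atol=1e-12)


def test_implied_moments_singular_structural_block_errors():
    spec = ModelSpec(factors={"a": ["x1", "x2"], "b": ["y1", "y2"]},
                     regressions={"b": ["a"]})
    pm = ParameterVector(spec)
    B = np.eye(2)
    with pytest.raises(ModelSpecError):
        sem.latent_covariance(np.zeros((4, 2)), B, np.eye(2))


# ---------------------------------------------------------------------------
# fitting oracles
# ---------------------------------------------------------------------------

def test_tetrad_closed_form_just_identified():
    r12, r13, r23 = 0.5, 0.4, 0.32
    R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])
    mom = moments_from_matrix(["a", "b", "c"], R, n=500)
    fit = sem.fit_dwls(ModelSpec(factors={"f": ["a", "b", "c"]}), mom)
    lams = fit.param_table.query("kind == 'lam'")["estimate"].to_numpy()
    expect = [np.sqrt(r12 * r13 / r23), np.sqrt(r12 * r23 / r13),
              np.sqrt(r13 * r23 / r12)]
    assert lams == pytest.approx(expect, abs=1e-6)
    assert fit.df == 0
    assert fit.discrepancy < 1e-12


def test_population_recovery_overidentified():
    lams = [0.5, 0.316, 0.566, 0.424]
    mom = moments_from_matrix(list("abcd"), one_factor_pop(lams), n=100_000)
    fit = sem.fit_dwls(ModelSpec(factors={"f": list("abcd")}), mom)
    est = fit.param_table.query("kind == 'lam'")["estimate"].to_numpy()
    assert est == pytest.approx(lams, abs=1e-6)
    assert fit.discrepancy < 1e-10
    assert fit.df == 2


def test_structural_population_recovery_and_identification_invariance():
    beta = -0.438
    lam_svd = [0.5, 0.316, 0.566, 0.424]
    lam_g = [0.7, 0.6, 0.65]
    Lam = np.zeros((7, 2))
    Lam[:4, 0] = lam_svd
    Lam[4:, 1] = lam_g
    V = np.array([[1, beta], [beta, 1]])
    R = Lam @ V @ Lam.T
    np.fill_diagonal(R, 1.0)
    names = list("abcdefg")
    mom = moments_from_matrix(names, R, n=100_000)
    stds = []
    for ident in (sem.UNIT_VARIANCE, sem.FIRST_LOADING):
        spec = ModelSpec(factors={"svd": names[:4], "g": names[4:]},
                         regressions={"g": ["svd"]}, identification=ident)
        fit = sem.fit_dwls(spec, mom)
        std = sem.standardize(fit)
        stds.append(std)
        assert std.paths["est"].iloc[0] == pytest.approx(beta, abs=1e-6)
        assert std.r2_latent["g"] == pytest.approx(beta ** 2, abs=1e-6)
    assert np.allclose(stds[0].loadings["est"], stds[1].loadings["est"],
                       atol=1e-6)


def test_not_identified_model_raises():
    mom = moments_from_matrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    with pytest.raises(ModelSpecError, match="not identified"):
        sem.fit_dwls(ModelSpec(factors={"f": ["a", "b"]}), mom)


def test_heywood_direction_is_flagged_not_fatal():
    R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.5], [0.9, 0.5, 1.0]])
    mom = moments_from_matrix(["a", "b", "c"], R, n=500)
    fit = sem.fit_dwls(ModelSpec(factors={"f": ["a", "b", "c"]}), mom)
    assert "a" in fit.heywood
    std = sem.standardize(fit)
    assert any(f.startswith("heywood") for f in std.flags)


def test_adjusted_chisq_zero_for_saturated_model():
    mom = moments_from_matrix(["a", "b", "c"],
                              one_factor_pop([0.6, 0.5, 0.4]), n=500)
    fit = sem.fit_dwls(ModelSpec(factors={"f": ["a", "b", "c"]}), mom)
    assert fit.df == 0
    assert fit.chisq_adjusted == 0.0


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_idempotent_on_standardized_fit():
    mom = moments_from_matrix(list("abcd"),
                              one_factor_pop([0.5, 0.6, 0.7, 0.4]), n=2000)
    fit = sem.fit_dwls(ModelSpec(factors={"f": list("abcd")}), mom)
    std = sem.standardize(fit)
    raw = fit.param_table.query("kind == 'lam'")["estimate"].to_numpy()
    assert np.allclose(std.loadings["est"], raw, atol=1e-10)


def test_standardize_rescales_unstandardized_parameters():
    # loading 2 on a factor with variance 0.25 -> explained variance 1 on a
    # unit-total-variance indicator -> standardized loading 1, communality 1
    spec = ModelSpec(factors={"f": ["a", "b"]},
                     identification=sem.FIRST_LOADING)
    pm = ParameterVector(spec)
    for e in pm.entries:
        if e.kind == "lam" and e.b == "a":
            e.value = 1.0       # fixed by the identification rule
        elif e.kind == "lam" and e.b == "b":
            e.value = 2.0
        elif e.kind == "psi":
            e.value = 0.25
    vec = sem._std_vector(spec, pm, pm.free_values())
    # entry order follows the parameter table: loading of a, then b
    assert vec[0] == pytest.approx(0.5, abs=1e-12)   # 1 * sd(f) / 1
    assert vec[1] == pytest.approx(1.0, abs=1e-12)   # 2 * sd(f) / 1


def test_standardized_ci_brackets_estimate(cohort_20k):
    mom = mixed_matrix(cohort_20k, cohort_20k.schema, sv.SVD_MARKERS)
    fit = sem.fit_dwls(ModelSpec(factors={"svd": sv.SVD_MARKERS}), mom)
    std = sem.standardize(fit)
    assert ((std.loadings["ci_low"] <= std.loadings["est"])
            & (std.loadings["est"] <= std.loadings["ci_high"])).all()
    assert (std.loadings["se"] > 0).all()


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def test_factor_scores_near_perfect_indicator():
    """An indicator with loading -> 1 and residual -> 0 dominates the
    score, which then equals that standardized indicator."""
    rng = np.random.default_rng(5)
    x = 3 + 2 * rng.standard_normal(2000)
    df = pd.DataFrame({
        "a": x,
        "b": x + 0.05 * rng.standard_normal(2000),
        "c": 0.3 * x + 2 * rng.standard_normal(2000),
    })
    schema = sv.VariableSchema([sv.VariableDef(v, "continuous")
                                for v in "abc"])
    mom = mixed_matrix(df, schema, ["a", "b", "c"], compute_gamma=False)
    fit = sem.fit_dwls(ModelSpec(factors={"f": ["a", "b", "c"]}), mom)
    scores = sem.factor_scores(fit, df, "f")
    z = (x - x.mean()) / x.std()
    assert np.corrcoef(scores, z)[0, 1] > 0.999


def test_factor_scores_equal_loadings_proportional_to_row_mean():
    """With exactly equal fitted loadings the regression weights are
    symmetric, so the score is proportional to the mean standardized
    indicator."""
    rng = np.random.default_rng(6)
    f = rng.standard_normal(2000)
    Y = 0.6 * f[:, None] + 0.8 * rng.standard_normal((2000, 3))
    df = pd.DataFrame(Y, columns=list("abc"))
    # fit at the population moments so the loadings are exactly equal
    mom = moments_from_matrix(list("abc"), one_factor_pop([0.6, 0.6, 0.6]),
                              n=2000)
    fit = sem.fit_dwls(ModelSpec(factors={"f": list("abc")}), mom)
    scores = sem.factor_scores(fit, df, "f")
    rowmean = ((Y - Y.mean(0)) / Y.std(0)).mean(axis=1)
    assert abs(np.corrcoef(scores, rowmean)[0, 1]) > 1 - 1e-10


def test_factor_scores_missing_handling(cohort_20k):
    df = cohort_20k.df.head(2000).copy()
    df.loc[df.index[:5], sv.SVD_MARKERS] = np.nan
    table = cohort_20k.replace_df(df)
    mom = mixed_matrix(table, table.schema, sv.SVD_MARKERS,
                       compute_gamma=False)
    fit = sem.fit_dwls(ModelSpec(factors={"svd": sv.SVD_MARKERS}), mom)
    scores = sem.factor_scores(fit, table, "svd")
    assert scores.iloc[:5].isna().all()
    assert scores.iloc[5:].notna().all()
    assert scores.iloc[5:].mean() == pytest.approx(0.0, abs=1e-9)


def test_factor_scores_match_implied_reliability_continuous():
    """For all-continuous indicators the score-truth correlation equals the
    model-implied score reliability sqrt(lambda' Sigma^-1 lambda)."""
    lams = np.array([0.7, 0.6, 0.5, 0.4])
    rng = np.random.default_rng(13)
    f = rng.standard_normal(30_000)
    Y = lams * f[:, None] + np.sqrt(1 - lams ** 2) \
        * rng.standard_normal((30_000, 4))
    df = pd.DataFrame(Y, columns=list("abcd"))
    schema = sv.VariableSchema([sv.VariableDef(v, "continuous")
                                for v in "abcd"])
    mom = mixed_matrix(df, schema, list("abcd"), compute_gamma=False)
    fit = sem.fit_dwls(ModelSpec(factors={"f": list("abcd")}), mom)
    scores = sem.factor_scores(fit, df, "f")
    r = np.corrcoef(scores, f)[0, 1]
    Sigma = one_factor_pop(lams)
    implied = np.sqrt(lams @ np.linalg.solve(Sigma, lams))
    assert r == pytest.approx(implied, abs=0.015)


def test_factor_scores_mixed_indicators_track_latent(cohort_20k):
    """Scores from mixed continuous/binary indicators correlate positively
    and substantially with the generating latent, below the continuous-only
    ceiling (binary indicators enter through coarsened conditional means)."""
    mom = mixed_matrix(cohort_20k, cohort_20k.schema, sv.SVD_MARKERS)
    fit = sem.fit_dwls(ModelSpec(factors={"svd": sv.SVD_MARKERS}), mom)
    scores = sem.factor_scores(fit, cohort_20k, "svd")
    r = np.corrcoef(scores, cohort_20k.df["_latent_svd"])[0, 1]
    lam = np.array([sv.default_generating_parameters().svd_loadings[v]
                    for v in sv.SVD_MARKERS])
    Sigma = one_factor_pop(lam)
    ceiling = np.sqrt(lam @ np.linalg.solve(Sigma, lam))
    assert 0.45 < r < ceiling
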