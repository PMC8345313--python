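"""Structural-equation engine: DWLS fitting of mixed-moment structures.

Models are confirmatory factor / latent regression systems in correlation
metric.  Observed exogenous covariates are carried as single-indicator
latents with unit loading; categorical indicators enter on their latent
response (probit) scale under the delta parameterization, so every
indicator's implied variance is 1 and residual variances are the unit
complement of the explained variance rather than free parameters.

Estimation minimizes the diagonally weighted least squares discrepancy

    F(theta) = sum_over_unique_moments (s - sigma(theta))^2 / w

with w the asymptotic variance of each pairwise correlation estimate.  The
test statistic is mean-and-variance adjusted (Satterthwaite style) using the
full asymptotic covariance of the sample moments; parameter standard errors
are sandwich-type.  This mirrors the WLSMV estimator conventional for
categorical SEM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares
from scipy.stats import norm

from .correlations import MixedCorrelationMatrix, category_means

logger = logging.getLogger("svdburden")

UNIT_VARIANCE = "unit_variance"
FIRST_LOADING = "first_loading"


class ModelSpecError(ValueError):
    """Ill-posed model specification (cycles, unknown names, ...)."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge after jittered restarts."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative SEM model.

    factors: latent name -> ordered indicator list.
    regressions: endogenous latent -> predictor names (latents or covariates).
    observed_exogenous: observed covariate columns, free to correlate with
        each other and with exogenous latents (and regressable onto outcomes).
    covariances: overrides for latent/covariate pairs: value ``"free"`` or a
        fixed float (e.g. 0.0 for orthogonality).
    identification: ``unit_variance`` (factor/disturbance variances fixed to
        1, all loadings free) or ``first_loading`` (first loading fixed 1).
    """

    factors: dict[str, list[str]]
    regressions: dict[str, list[str]] = field(default_factory=dict)
    observed_exogenous: list[str] = field(default_factory=list)
    covariances: dict[tuple[str, str], object] = field(default_factory=dict)
    identification: str = UNIT_VARIANCE

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def entities(self) -> list[str]:
        """All latent entities: declared factors then covariate pseudo-factors."""
        return list(self.factors) + list(self.observed_exogenous)

    @property
    def endogenous(self) -> list[str]:
        return list(self.regressions)

    @property
    def exogenous(self) -> list[str]:
        endo = set(self.regressions)
        return [e for e in self.entities if e not in endo]

    @property
    def indicator_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for inds in self.factors.values():
            for i in inds:
                seen.setdefault(i)
        for c in self.observed_exogenous:
            seen.setdefault(c)
        return list(seen)

    def validate(self) -> None:
        if self.identification not in (UNIT_VARIANCE, FIRST_LOADING):
            raise ModelSpecError(f"unknown identification {self.identification!r}")
        ents = set(self.entities)
        if len(ents) != len(self.entities):
            raise ModelSpecError("duplicate factor/covariate names")
        for f, inds in self.factors.items():
            if not inds:
                raise ModelSpecError(f"factor {f!r} has no indicators")
        for out, preds in self.regressions.items():
            if out not in self.factors:
                raise ModelSpecError(f"regression outcome {out!r} is not a factor")
            for p in preds:
                if p not in ents:
                    raise ModelSpecError(f"unknown predictor {p!r}")
        # acyclicity of the structural graph
        color: dict[str, int] = {}

        def visit(v):
            color[v] = 1
            for p in self.regressions.get(v, []):
                if color.get(p) == 1:
                    raise ModelSpecError("structural graph contains a cycle")
                if color.get(p, 0) == 0:
                    visit(p)
            color[v] = 2

        for v in self.regressions:
            if color.get(v, 0) == 0:
                visit(v)

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "factors": {k: list(v) for k, v in self.factors.items()},
            "regressions": {k: list(v) for k, v in self.regressions.items()},
            "observed_exogenous": list(self.observed_exogenous),
            "covariances": {f"{a}~~{b}": v for (a, b), v in self.covariances.items()},
            "identification": self.identification,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        doc = yaml.safe_load(text)
        cov = {}
        for key, v in (doc.get("covariances") or {}).items():
            a, b = key.split("~~")
            cov[(a, b)] = v
        return cls(
            factors=doc.get("factors", {}),
            regressions=doc.get("regressions", {}),
            observed_exogenous=doc.get("observed_exogenous", []),
            covariances=cov,
            identification=doc.get("identification", UNIT_VARIANCE),
        )


# ---------------------------------------------------------------------------
# parameter vector
# ---------------------------------------------------------------------------

@dataclass
class ParamEntry:
    kind: str     # lam | beta | psi
    a: str
    b: str
    value: float
    free: bool
    lo: float = -np.inf
    hi: float = np.inf

    @property
    def label(self) -> str:
        op = {"lam": "=~", "beta": "~", "psi": "~~"}[self.kind]
        return f"{self.a}{op}{self.b}"


class ParameterVector:
    """Named flat parameter vector with free/fixed status, mapping to the
    (Lambda, B, Psi) matrices of the linear structural model."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.entries: list[ParamEntry] = []
        first_loading = spec.identification == FIRST_LOADING
        endo = set(spec.endogenous)

        for f, inds in spec.factors.items():
            for pos, ind in enumerate(inds):
                fixed_one = first_loading and pos == 0
                self.entries.append(ParamEntry(
                    "lam", f, ind, 1.0 if fixed_one else 0.4,
                    free=not fixed_one, lo=-1.5, hi=1.5))
        for c in spec.observed_exogenous:
            self.entries.append(ParamEntry("lam", c, c, 1.0, free=False))

        for out, preds in spec.regressions.items():
            for p in preds:
                self.entries.append(ParamEntry("beta", out, p, 0.0, free=True,
                                               lo=-3.0, hi=3.0))

        ents = spec.entities
        overrides = {frozenset(k): v for k, v in spec.covariances.items()}
        exo = set(spec.exogenous)
        for i, a in enumerate(ents):
            for b in ents[i:]:
                key = frozenset((a, b)) if a != b else frozenset((a,))
                ov = overrides.get(key)
                if a == b:
                    if a in spec.observed_exogenous:
                        self.entries.append(ParamEntry("psi", a, a, 1.0, False))
                    elif first_loading:
                        self.entries.append(ParamEntry("psi", a, a, 1.0, True,
                                                       lo=1e-6, hi=25.0))
                    else:
                        # unit variance (exogenous) / unit disturbance (endo)
                        self.entries.append(ParamEntry("psi", a, a, 1.0, False))
                    continue
                both_cov = a in spec.observed_exogenous and b in spec.observed_exogenous
                default_free = (a in exo and b in exo)
                if ov == "free":
                    free, val = True, 0.0
                elif ov is not None:
                    free, val = False, float(ov)
                elif default_free:
                    free, val = True, 0.0
                else:
                    free, val = False, 0.0
                if free or val != 0.0 or both_cov:
                    self.entries.append(ParamEntry("psi", a, b, val, free,
                                                   lo=-0.999, hi=0.999))

        self._free_idx = [i for i, e in enumerate(self.entries) if e.free]
        self._ent_index = {e: i for i, e in enumerate(spec.entities)}
        self._ind_index = {v: i for i, v in enumerate(spec.indicator_order)}

    # -- flat vector round trip ---------------------------------------------
    @property
    def n_free(self) -> int:
        return len(self._free_idx)

    def free_values(self) -> np.ndarray:
        return np.array([self.entries[i].value for i in self._free_idx])

    def free_labels(self) -> list[str]:
        return [self.entries[i].label for i in self._free_idx]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.entries[i].lo for i in self._free_idx])
        hi = np.array([self.entries[i].hi for i in self._free_idx])
        return lo, hi

    def set_free(self, theta: np.ndarray) -> None:
        for i, v in zip(self._free_idx, theta):
            self.entries[i].value = float(v)

    def matrices(self, theta: np.ndarray | None = None):
        """(Lambda, B, Psi) at the stored (or supplied) free values."""
        if theta is not None:
            vals = {i: float(v) for i, v in zip(self._free_idx, theta)}
        else:
            vals = {}
        ents = self.spec.entities
        m = len(ents)
        p = len(self._ind_index)
        Lam = np.zeros((p, m))
        B = np.zeros((m, m))
        Psi = np.zeros((m, m))
        for i, e in enumerate(self.entries):
            v = vals.get(i, e.value)
            if e.kind == "lam":
                Lam[self._ind_index[e.b], self._ent_index[e.a]] = v
            elif e.kind == "beta":
                B[self._ent_index[e.a], self._ent_index[e.b]] = v
            else:
                ia, ib = self._ent_index[e.a], self._ent_index[e.b]
                Psi[ia, ib] = Psi[ib, ia] = v
        return Lam, B, Psi

    def table(self, se: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        k = 0
        for e in self.entries:
            s = np.nan
            if e.free and se is not None:
                s = se[k]
            if e.free:
                k += 1
            rows.append({"parameter": e.label, "kind": e.kind, "lhs": e.a,
                         "rhs": e.b, "estimate": e.value, "free": e.free,
                         "se": s})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def latent_covariance(Lam, B, Psi) -> np.ndarray:
    m = B.shape[0]
    I = np.eye(m)
    try:
        A = np.linalg.inv(I - B)
    except np.linalg.LinAlgError as exc:
        raise ModelSpecError("(I - B) is singular: cyclic or ill-posed "
                             "structural block") from exc
    return A @ Psi @ A.T


def implied_moments(spec: ModelSpec, params: ParameterVector,
                    theta: np.ndarray | None = None) -> np.ndarray:
    """Model-implied indicator correlation matrix (latent-response scale).

    Residual variances are the unit complement of the explained variance;
    where explained variance exceeds 1 (Heywood direction) the diagonal
    exceeds 1 and fitting/standardization flags it.
    """
    Lam, B, Psi = params.matrices(theta)
    V = latent_covariance(Lam, B, Psi)
    S = Lam @ V @ Lam.T
    d = np.diag(S).copy()
    np.fill_diagonal(S, np.maximum(d, 1.0))
    return S


# ---------------------------------------------------------------------------
# fit result containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    spec: ModelSpec
    params: ParameterVector
    param_table: pd.DataFrame
    standard_errors: np.ndarray
    cov_params: np.ndarray
    discrepancy: float
    chisq_unadjusted: float
    chisq_adjusted: float
    df: int
    df_adjusted: float
    n_effective: int
    converged: bool
    n_iterations: int
    gradient_norm: float
    heywood: list[str]
    moments: MixedCorrelationMatrix
    implied: np.ndarray
    residuals: np.ndarray          # s - sigma(theta_hat), vech order

    @property
    def variables(self) -> list[str]:
        return self.spec.indicator_order

    def to_json(self) -> str:
        """Headline fit statistics as JSON (parameters via ``param_table``)."""
        import json
        return json.dumps({
            "discrepancy": self.discrepancy,
            "chisq_unadjusted": self.chisq_unadjusted,
            "chisq_adjusted": self.chisq_adjusted,
            "df": self.df, "df_adjusted": self.df_adjusted,
            "n_effective": self.n_effective,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "gradient_norm": self.gradient_norm,
            "heywood": self.heywood,
        }, indent=1)


@dataclass
class StandardizedSolution:
    loadings: pd.DataFrame         # factor, indicator, est, se, ci, p
    paths: pd.DataFrame            # outcome, predictor, est, se, ci, p
    exo_correlations: pd.DataFrame
    r2_latent: dict[str, float]
    r2_indicator: dict[str, float]
    implied_correlations: np.ndarray
    flags: list[str]

    def to_csv(self, prefix: str) -> None:
        """Flat parameter tables: <prefix>_loadings.csv / _paths.csv /
        _correlations.csv."""
        self.loadings.to_csv(f"{prefix}_loadings.csv", index=False)
        self.paths.to_csv(f"{prefix}_paths.csv", index=False)
        self.exo_correlations.to_csv(f"{prefix}_correlations.csv",
                                     index=False)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _sigma_vech(spec, params, theta, tri):
    S = implied_moments(spec, params, theta)
    return S[tri]


def fit_dwls(spec: ModelSpec, moments: MixedCorrelationMatrix,
             max_restarts: int = 5, gradient_tol: float = 1e-6,
             max_iter: int = 500) -> FitResult:
    """Fit a model by diagonally weighted least squares on mixed moments.

    Quasi-Newton trust-region least squares with central-difference
    Jacobian; on non-convergence the start point is jittered and the fit
    retried (deterministically) up to ``max_restarts`` times.
    """
    order = spec.indicator_order
    if list(moments.variables) != order:
        moments = moments.submatrix(order)
    pmat = ParameterVector(spec)
    tri = np.triu_indices(len(order), k=1)
    s = moments.estimates[tri]
    w = np.maximum(moments.asymptotic_variances[tri], 1e-12)
    sw = np.sqrt(w)
    n_mom = len(s)
    if pmat.n_free > n_mom:
        raise ModelSpecError(
            f"model not identified: {pmat.n_free} free parameters exceed "
            f"{n_mom} unique moments")

    def resid(theta):
        return (_sigma_vech(spec, pmat, theta, tri) - s) / sw

    x0_base = pmat.free_values()
    # initialize observed-covariate correlations at their sample values
    labels = pmat.free_labels()
    for t, lab in enumerate(labels):
        if "~~" in lab:
            a, b = lab.split("~~")
            if (a in spec.observed_exogenous and b in spec.observed_exogenous):
                x0_base[t] = moments.estimates[order.index(a), order.index(b)]
    lo, hi = pmat.bounds()

    best = None
    rng = np.random.default_rng(20240540)
    for attempt in range(max_restarts + 1):
        x0 = x0_base if attempt == 0 else np.clip(
            x0_base + rng.normal(0, 0.1 + 0.05 * attempt, x0_base.size), lo, hi)
        res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=max_iter * max(1, pmat.n_free))
        # scale-invariant convergence: Newton decrement of the weighted
        # objective relative to its value (the raw gradient norm depends on
        # the weight scale and would mislabel converged fits)
        g = res.jac.T @ res.fun
        A_gn = res.jac.T @ res.jac
        decrement = float(g @ np.linalg.pinv(A_gn) @ g)
        grad_norm = decrement / (1.0 + float(2 * res.cost))
        ok = res.success and (grad_norm < gradient_tol or res.cost < 1e-18)
        if best is None or res.cost < best[0].cost - 1e-12:
            best = (res, grad_norm, ok)
        if ok:
            best = (res, grad_norm, True)
            break
        logger.info("fit_dwls restart %d (gradient norm %.2e)", attempt + 1,
                    grad_norm)
    res, grad_norm, converged = best
    theta = res.x
    pmat.set_free(theta)

    # sign convention: first indicator of every common factor loads positively
    flips = _canonical_signs(spec, pmat)

    F_hat = float(2 * res.cost)           # sum of squared weighted residuals
    sigma = _sigma_vech(spec, pmat, None, tri)
    residuals = s - sigma

    # central-difference Jacobian of sigma wrt free params at the solution
    J = np.empty((n_mom, pmat.n_free))
    h = 1e-6
    th = pmat.free_values()
    for k in range(pmat.n_free):
        tp = th.copy(); tp[k] += h
        tm = th.copy(); tm[k] -= h
        J[:, k] = (_sigma_vech(spec, pmat, tp, tri)
                   - _sigma_vech(spec, pmat, tm, tri)) / (2 * h)

    Wd = 1.0 / w
    A = J.T @ (J * Wd[:, None])
    # empirical identification check: a numerically singular information
    # matrix means some parameter direction is unconstrained by the moments
    # (e.g. a factor whose loadings all vanish); refuse to report silently
    eigs = np.linalg.eigvalsh(A)
    if pmat.n_free and eigs[0] < 1e-8 * max(eigs[-1], 1e-300):
        logger.warning("model empirically non-identified (information "
                       "condition %.2e); flagging fit", eigs[0] / eigs[-1])
        converged = False
    Ainv = np.linalg.pinv(A)
    gamma = moments.gamma
    if gamma is None:
        gamma = np.diag(w)
    JW = J * Wd[:, None]
    cov = Ainv @ (JW.T @ gamma @ JW) @ Ainv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    df = n_mom - pmat.n_free
    if df > 0:
        U = np.diag(Wd) - JW @ Ainv @ JW.T
        M = U @ gamma
        tr1 = float(np.trace(M))
        tr2 = float(np.trace(M @ M))
        chisq_adj = F_hat * tr1 / tr2 if tr2 > 0 else 0.0
        df_adj = tr1 ** 2 / tr2 if tr2 > 0 else 0.0
    else:
        chisq_adj = 0.0
        df_adj = 0.0

    S_imp = implied_moments(spec, pmat)
    raw_diag = np.diag(pmat.matrices()[0] @ latent_covariance(*pmat.matrices())
                       @ pmat.matrices()[0].T)
    heywood = [order[i] for i in range(len(order)) if raw_diag[i] > 1 + 1e-8]
    if heywood:
        logger.warning("Heywood direction (explained variance > 1) for: %s",
                       ", ".join(heywood))

    n_eff = int(np.median(moments.pair_n[tri])) if n_mom else 0
    return FitResult(
        spec=spec, params=pmat, param_table=pmat.table(se),
        standard_errors=se, cov_params=cov, discrepancy=F_hat,
        chisq_unadjusted=F_hat, chisq_adjusted=chisq_adj, df=df,
        df_adjusted=df_adj, n_effective=n_eff, converged=converged,
        n_iterations=int(res.nfev), gradient_norm=grad_norm,
        heywood=heywood, moments=moments, implied=S_imp, residuals=residuals)


def _canonical_signs(spec: ModelSpec, pmat: ParameterVector) -> dict[str, int]:
    """Flip factors so each factor's first indicator loads positively."""
    flips = {}
    for f, inds in spec.factors.items():
        lead = next(e for e in pmat.entries
                    if e.kind == "lam" and e.a == f and e.b == inds[0])
        flips[f] = -1 if lead.value < 0 else 1
    for e in pmat.entries:
        if e.kind == "lam" and flips.get(e.a, 1) < 0:
            e.value = -e.value
        elif e.kind == "beta":
            e.value *= flips.get(e.a, 1) * flips.get(e.b, 1)
        elif e.kind == "psi" and e.a != e.b:
            e.value *= flips.get(e.a, 1) * flips.get(e.b, 1)
    return flips


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def _std_vector(spec, pmat, theta):
    """All standardized quantities as one vector (for the delta method)."""
    Lam, B, Psi = pmat.matrices(theta)
    V = latent_covariance(Lam, B, Psi)
    sd_lat = np.sqrt(np.maximum(np.diag(V), 1e-300))
    raw_diag = np.diag(Lam @ V @ Lam.T)
    sd_ind = np.sqrt(np.maximum(raw_diag, 1.0))
    out = []
    ind_index = pmat._ind_index
    ent_index = pmat._ent_index
    for e in pmat.entries:
        if e.kind == "lam" and e.a in spec.factors:
            lam = (Lam[ind_index[e.b], ent_index[e.a]]
                   * sd_lat[ent_index[e.a]] / sd_ind[ind_index[e.b]])
            out.append(lam)
        elif e.kind == "beta":
            out.append(B[ent_index[e.a], ent_index[e.b]]
                       * sd_lat[ent_index[e.b]] / sd_lat[ent_index[e.a]])
        elif e.kind == "psi" and e.a != e.b:
            out.append(V[ent_index[e.a], ent_index[e.b]]
                       / (sd_lat[ent_index[e.a]] * sd_lat[ent_index[e.b]]))
    return np.array(out)


def standardize(fit: FitResult, ci_level: float = 0.95) -> StandardizedSolution:
    """Standardized estimates with delta-method SEs, Wald CIs and R-squared."""
    spec, pmat = fit.spec, fit.params
    theta = pmat.free_values()
    est = _std_vector(spec, pmat, theta)
    G = np.empty((est.size, pmat.n_free))
    h = 1e-6
    for k in range(pmat.n_free):
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        G[:, k] = (_std_vector(spec, pmat, tp) - _std_vector(spec, pmat, tm)) / (2 * h)
    var = np.einsum("ij,jk,ik->i", G, fit.cov_params, G)
    se = np.sqrt(np.maximum(var, 0.0))
    zq = norm.ppf(0.5 + ci_level / 2)

    Lam, B, Psi = pmat.matrices()
    V = latent_covariance(Lam, B, Psi)
    sd_lat = np.sqrt(np.maximum(np.diag(V), 1e-300))
    raw_diag = np.diag(Lam @ V @ Lam.T)
    total = np.maximum(raw_diag, 1.0)
    flags = [f"heywood:{v}" for v in fit.heywood]
    if not fit.converged:
        flags.append("non-converged")
    # a factor whose standardized loadings all vanish measures nothing;
    # structural paths involving it are then empirically meaningless
    k0 = 0
    by_factor: dict[str, float] = {}
    for e in pmat.entries:
        if e.kind == "lam" and e.a in spec.factors:
            by_factor[e.a] = max(by_factor.get(e.a, 0.0), abs(est[k0]))
            k0 += 1
        elif e.kind in ("beta",) or (e.kind == "psi" and e.a != e.b):
            k0 += 1
    for f, mx in by_factor.items():
        if mx < 0.1:
            flags.append(f"vacuous-factor:{f}")

    rows_l, rows_p, rows_c = [], [], []
    k = 0
    for e in pmat.entries:
        if e.kind == "lam" and e.a in spec.factors:
            rec = {"factor": e.a, "indicator": e.b, "est": est[k], "se": se[k],
                   "ci_low": est[k] - zq * se[k], "ci_high": est[k] + zq * se[k],
                   "p": 2 * norm.sf(abs(est[k]) / se[k]) if se[k] > 0 else np.nan}
            rows_l.append(rec)
            k += 1
        elif e.kind == "beta":
            rec = {"outcome": e.a, "predictor": e.b, "est": est[k], "se": se[k],
                   "ci_low": est[k] - zq * se[k], "ci_high": est[k] + zq * se[k],
                   "p": 2 * norm.sf(abs(est[k]) / se[k]) if se[k] > 0 else np.nan}
            rows_p.append(rec)
            k += 1
        elif e.kind == "psi" and e.a != e.b:
            rec = {"a": e.a, "b": e.b, "est": est[k], "se": se[k],
                   "ci_low": est[k] - zq * se[k], "ci_high": est[k] + zq * se[k],
                   "p": 2 * norm.sf(abs(est[k]) / se[k]) if se[k] > 0 else np.nan}
            rows_c.append(rec)
            k += 1

    ent_index = pmat._ent_index
    r2_latent = {o: 1.0 - Psi[ent_index[o], ent_index[o]] / V[ent_index[o], ent_index[o]]
                 for o in spec.endogenous}
    r2_ind = {v: float(raw_diag[i] / total[i])
              for i, v in enumerate(spec.indicator_order)}
    D = np.diag(1.0 / np.sqrt(total))
    implied_corr = D @ (Lam @ V @ Lam.T + np.diag(total - raw_diag)) @ D

    return StandardizedSolution(
        loadings=pd.DataFrame(rows_l), paths=pd.DataFrame(rows_p),
        exo_correlations=pd.DataFrame(rows_c), r2_latent=r2_latent,
        r2_indicator=r2_ind, implied_correlations=implied_corr, flags=flags)


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def factor_scores(fit: FitResult, table, factor: str) -> pd.Series:
    """Regression-method factor scores, standardized over scored rows.

    Continuous indicators are z-scored; categorical indicators are replaced
    by the conditional mean of their latent response given the observed
    category (truncated-normal mean between the estimated thresholds).
    Rows missing some indicators use the available-indicator submatrix;
    rows missing all indicators receive a missing score.
    """
    df = table.df if hasattr(table, "df") else table
    spec, pmat = fit.spec, fit.params
    inds = [v for v in spec.factors.get(factor, [])] or spec.indicator_order
    order = spec.indicator_order
    Lam, B, Psi = pmat.matrices()
    V = latent_covariance(Lam, B, Psi)
    raw_diag = np.diag(Lam @ V @ Lam.T)
    total = np.maximum(raw_diag, 1.0)
    D = np.diag(1.0 / np.sqrt(total))
    Sigma = D @ (Lam @ V @ Lam.T + np.diag(total - raw_diag)) @ D
    # cov(standardized indicator, factor) / sd(factor): correlation metric
    f_idx = pmat._ent_index[factor]
    cov_yf = (Lam @ V)[:, f_idx] / np.sqrt(total) / np.sqrt(V[f_idx, f_idx])

    use = [order.index(v) for v in inds]
    Y = np.full((len(df), len(use)), np.nan)
    for c, vi in enumerate(use):
        name = order[vi]
        col = df[name].to_numpy(dtype=float)
        if name in fit.moments.thresholds:
            tau = fit.moments.thresholds[name]
            means = category_means(tau)
            obs = ~np.isnan(col)
            vals = np.full(col.shape, np.nan)
            vals[obs] = means[col[obs].astype(int)]
            Y[:, c] = vals
        else:
            m = np.nanmean(col)
            sd = np.nanstd(col)
            if sd == 0:
                raise ValueError(f"indicator {name!r} has zero variance")
            Y[:, c] = (col - m) / sd

    Sig_sub = Sigma[np.ix_(use, use)]
    cov_sub = cov_yf[use]
    scores = np.full(len(df), np.nan)
    obs_mask = ~np.isnan(Y)
    pats, inverse = np.unique(obs_mask, axis=0, return_inverse=True)
    for pi, pat in enumerate(pats):
        rows = inverse == pi
        if not pat.any():
            continue
        a = np.linalg.solve(Sig_sub[np.ix_(pat, pat)], cov_sub[pat])
        scores[rows] = Y[np.ix_(rows, pat)] @ a
    n_missing = int(np.isnan(scores).sum())
    if n_missing:
        logger.info("factor_scores: %d rows with no scorable indicators", n_missing)
    ok = ~np.isnan(scores)
    mu, sd = scores[ok].mean(), scores[ok].std()
    if sd > 0:
        scores[ok] = (scores[ok] - mu) / sd
    return pd.Series(scores, index=df.index, name=f"{factor}_score")
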