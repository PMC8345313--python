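"""Latent-correlation estimation for mixed continuous/binary/ordinal data.

Categorical variables are modelled as discretizations of standard-normal
continua at threshold cut points tau.  Pairwise association is then measured
on the latent scale: Pearson for continuous-continuous pairs, polyserial for
continuous-categorical, polychoric (tetrachoric in the 2x2 case) for
categorical-categorical.  Estimation is two-stage: thresholds are fixed from
the univariate margins, then the latent correlation maximizes the bivariate
normal likelihood of the observed pair.

The resulting matrix of pairwise estimates, together with per-estimate
asymptotic variances (the diagonal weights of DWLS fitting) and the full
asymptotic covariance of the estimates (needed for mean-and-variance adjusted
test statistics and sandwich standard errors), is the input moment structure
for the structural-equation engine.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import norm

logger = logging.getLogger("svdburden")

CONTINUOUS = "continuous"
BINARY = "binary"
ORDINAL = "ordinal"
IDENTIFIER = "identifier"

#: latent correlations are clamped to +/- (1 - BOUNDARY_EPS) rather than
#: allowed to diverge when a contingency table implies perfect association
BOUNDARY_EPS = 1e-6

#: minimum pairwise-complete sample size for any pairwise estimate
MIN_PAIR_N = 10


class DegenerateCategoryError(ValueError):
    """A declared category carries no observed probability mass."""


class InsufficientDataError(ValueError):
    """Too few pairwise-complete observations to estimate an association."""


class DegenerateInputError(ValueError):
    """A continuous column with zero variance (or similar) was supplied."""


# ---------------------------------------------------------------------------
# variable schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableDef:
    name: str
    measurement: str          # continuous | binary | ordinal
    n_categories: int = 0     # for ordinal; binary implies 2
    role: str = "indicator"   # indicator | covariate | auxiliary

    def __post_init__(self):
        if self.measurement not in (CONTINUOUS, BINARY, ORDINAL, IDENTIFIER):
            raise ValueError(f"unknown measurement type {self.measurement!r}")
        if self.measurement == ORDINAL and self.n_categories < 2:
            raise ValueError(f"ordinal variable {self.name!r} needs k >= 2")

    @property
    def categorical(self) -> bool:
        return self.measurement in (BINARY, ORDINAL)

    @property
    def k(self) -> int:
        return 2 if self.measurement == BINARY else self.n_categories


class VariableSchema:
    """Ordered mapping from column name to its measurement declaration."""

    def __init__(self, variables: list[VariableDef]):
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")
        self._vars = {v.name: v for v in variables}

    def __getitem__(self, name: str) -> VariableDef:
        return self._vars[name]

    def __contains__(self, name: str) -> bool:
        return name in self._vars

    def __iter__(self):
        return iter(self._vars.values())

    @property
    def names(self) -> list[str]:
        return list(self._vars)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": v.name,
                    "measurement": v.measurement,
                    "n_categories": v.n_categories,
                    "role": v.role,
                }
                for v in self._vars.values()
            ],
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "VariableSchema":
        return cls([VariableDef(**d) for d in json.loads(text)])


# ---------------------------------------------------------------------------
# bivariate normal probabilities (Owen's T identity, accurate to ~1e-14)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the exact Owen's-T representation; elementwise over broadcast
    arrays.  |rho| may be 1 (Frechet bounds).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if rho >= 1.0 - 1e-14:
        return np.minimum(ndtr(h), ndtr(k))
    if rho <= -1.0 + 1e-14:
        return np.maximum(0.0, ndtr(h) + ndtr(k) - 1.0)

    # resolve exact zeros to +0-side limits; the CDF is continuous so the
    # perturbation error is O(1e-12)
    hz = np.where(h == 0.0, 1e-12, h)
    kz = np.where(k == 0.0, 1e-12, k)
    denom = np.sqrt(1.0 - rho * rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        ah = np.nan_to_num((kz - rho * hz) / (hz * denom), nan=0.0)
        ak = np.nan_to_num((hz - rho * kz) / (kz * denom), nan=0.0)
    # delta term of the identity: 1/2 when the quadrant correction applies
    delta = np.where(hz * kz > 0, 0.0, 0.5)
    finite = np.isfinite(hz) & np.isfinite(kz)
    out = np.where(
        finite,
        0.5 * (ndtr(hz) + ndtr(kz))
        - owens_t(np.where(finite, hz, 0.0), ah)
        - owens_t(np.where(finite, kz, 0.0), ak)
        - delta,
        0.0,
    )

    # infinite limits reduce to univariate margins
    out = np.where(np.isposinf(h), ndtr(k), out)
    out = np.where(np.isposinf(k), np.where(np.isposinf(h), 1.0, ndtr(h)), out)
    out = np.where(np.isneginf(h) | np.isneginf(k), 0.0, out)
    return np.clip(out, 0.0, 1.0)


def bvn_rect_prob(a_lo, a_hi, b_lo, b_hi, rho):
    """P(a_lo < X <= a_hi, b_lo < Y <= b_hi) for correlation rho."""
    p = (
        bvn_cdf(a_hi, b_hi, rho)
        - bvn_cdf(a_lo, b_hi, rho)
        - bvn_cdf(a_hi, b_lo, rho)
        + bvn_cdf(a_lo, b_lo, rho)
    )
    return np.clip(p, 0.0, 1.0)


def cell_probabilities(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """kx-by-ky table of bivariate-normal cell probabilities."""
    cx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    cy = np.concatenate(([-np.inf], tau_y, [np.inf]))
    F = bvn_cdf(cx[:, None], cy[None, :], rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def estimate_thresholds(column, n_categories: int | None = None,
                        name: str = "column") -> np.ndarray:
    """Thresholds tau_j = ndtri(cumulative proportion) from observed values.

    `column` holds integer category codes 0..k-1 with NaN for missing.  If
    `n_categories` is given, every declared category must carry observed
    mass; otherwise k is the highest observed code + 1.
    """
    x = np.asarray(column, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise InsufficientDataError(f"{name}: no observed values")
    codes = x.astype(int)
    k = n_categories if n_categories is not None else int(codes.max()) + 1
    counts = np.bincount(codes, minlength=k)
    if len(counts) > k:
        raise ValueError(f"{name}: observed code exceeds declared k={k}")
    zero = np.nonzero(counts == 0)[0]
    if zero.size:
        raise DegenerateCategoryError(
            f"{name}: category {zero[0]} has no observed mass")
    if k < 2:
        raise DegenerateCategoryError(f"{name}: fewer than 2 observed categories")
    cum = np.cumsum(counts)[:-1] / codes.size
    return ndtri(cum)


def thresholds_from_proportions(props) -> np.ndarray:
    """tau from a vector of category proportions (sums to 1)."""
    p = np.asarray(props, dtype=float)
    cum = np.cumsum(p)[:-1]
    return ndtri(np.clip(cum, 1e-12, 1 - 1e-12))


def category_means(tau: np.ndarray) -> np.ndarray:
    """E[Z | category] for a standard normal cut at tau (truncated means)."""
    cuts = np.concatenate(([-np.inf], tau, [np.inf]))
    dens = norm.pdf(cuts)
    dens[~np.isfinite(cuts)] = 0.0
    probs = np.diff(ndtr(cuts))
    probs = np.maximum(probs, 1e-300)
    return (dens[:-1] - dens[1:]) / probs


# ---------------------------------------------------------------------------
# pairwise estimators
# ---------------------------------------------------------------------------

@dataclass
class PairEstimate:
    rho: float
    avar: float                 # variance of the estimate (DWLS weight source)
    pair_type: str              # pearson | polyserial | polychoric
    n: int
    boundary: bool = False
    psi: np.ndarray | None = None   # per-observation influence values


def _finish(rho: float) -> tuple[float, bool]:
    lim = 1.0 - BOUNDARY_EPS
    # a bounded optimizer stops strictly inside the bracket and degenerate
    # (deterministic) pairs can have their finite-sample optimum slightly
    # inside it, so boundary detection is deliberately wider than the clamp
    if abs(rho) >= 1.0 - 1e-4:
        warnings.warn("latent correlation at boundary; clamped", stacklevel=3)
        return float(np.sign(rho) * lim), True
    return float(rho), False


def pearson_corr(x, y) -> PairEstimate:
    """Pearson correlation with its influence function.

    avar uses the normal-theory (1-r^2)^2 / n form as the DWLS weight
    default; the influence values feed the full asymptotic covariance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = ~(np.isnan(x) | np.isnan(y))
    n = int(m.sum())
    if n < MIN_PAIR_N:
        raise InsufficientDataError(f"pairwise n={n} below floor {MIN_PAIR_N}")
    xs, ys = x[m], y[m]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance in a continuous column")
    zx = (xs - xs.mean()) / sx
    zy = (ys - ys.mean()) / sy
    r = float(np.clip(np.mean(zx * zy), -1.0, 1.0))
    r, boundary = _finish(r)
    psi = np.full(x.shape, np.nan)
    psi[m] = zx * zy - 0.5 * r * (zx ** 2 + zy ** 2)
    avar = (1.0 - r * r) ** 2 / n
    return PairEstimate(r, avar, "pearson", n, boundary, psi)


def _polychoric_scores(tau_x, tau_y, rho, eps=1e-6):
    """Per-cell score d log pi / d rho (central difference)."""
    P1 = cell_probabilities(tau_x, tau_y, rho + eps)
    P0 = cell_probabilities(tau_x, tau_y, rho - eps)
    P = cell_probabilities(tau_x, tau_y, rho)
    return (P1 - P0) / (2 * eps) / np.maximum(P, 1e-300)


def polychoric_corr(x, y, kx: int | None = None, ky: int | None = None,
                    compute_if: bool = True) -> tuple[PairEstimate, dict]:
    """Two-stage polychoric (tetrachoric for 2x2) correlation.

    Thresholds are fixed at the pairwise-complete margins; rho maximizes the
    contingency-table likelihood under the bivariate-normal model.  Returns
    the estimate plus a dict with the thresholds used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = ~(np.isnan(x) | np.isnan(y))
    n = int(m.sum())
    if n < MIN_PAIR_N:
        raise InsufficientDataError(f"pairwise n={n} below floor {MIN_PAIR_N}")
    xs = x[m].astype(int)
    ys = y[m].astype(int)
    tau_x = estimate_thresholds(xs, kx, name="x")
    tau_y = estimate_thresholds(ys, ky, name="y")
    kx = len(tau_x) + 1
    ky = len(tau_y) + 1
    counts = np.bincount(xs * ky + ys, minlength=kx * ky).reshape(kx, ky)

    def nll(rho):
        P = cell_probabilities(tau_x, tau_y, rho)
        # tiny ridge breaks ties toward lower |rho| on flat likelihoods
        return -np.sum(counts * np.log(np.maximum(P, 1e-300))) + 1e-10 * rho ** 2

    lim = 1.0 - BOUNDARY_EPS
    res = minimize_scalar(nll, bounds=(-lim, lim), method="bounded",
                          options={"xatol": 1e-10})
    rho, boundary = _finish(res.x)

    # observed-information variance (rho | fixed thresholds)
    h = 1e-4
    d2 = (nll(min(rho + h, lim)) - 2 * nll(rho) + nll(max(rho - h, -lim))) / h ** 2
    avar = 1.0 / d2 if d2 > 0 else (1 - rho * rho) ** 2 / n

    psi = None
    if compute_if:
        eps = 1e-4
        Pn = counts / n
        s_cell = _polychoric_scores(tau_x, tau_y, rho)
        rp, rm = min(rho + eps, lim), max(rho - eps, -lim)
        sp = _polychoric_scores(tau_x, tau_y, rp)
        sm = _polychoric_scores(tau_x, tau_y, rm)
        H = np.sum(Pn * (sp - sm)) / (rp - rm)
        # two-stage correction for estimated thresholds
        extra = np.zeros(n)
        for tau, vals, on_x in ((tau_x, xs, True), (tau_y, ys, False)):
            cum = np.cumsum(np.bincount(vals, minlength=len(tau) + 1))[:-1] / n
            for j in range(len(tau)):
                tp = tau.copy(); tp[j] += eps
                tm_ = tau.copy(); tm_[j] -= eps
                if on_x:
                    s1 = _polychoric_scores(tp, tau_y, rho)
                    s0 = _polychoric_scores(tm_, tau_y, rho)
                else:
                    s1 = _polychoric_scores(tau_x, tp, rho)
                    s0 = _polychoric_scores(tau_x, tm_, rho)
                J = np.sum(Pn * (s1 - s0)) / (2 * eps)
                if_tau = ((vals <= j).astype(float) - cum[j]) / norm.pdf(tau[j])
                extra += J * if_tau
        psi = np.full(x.shape, np.nan)
        psi[m] = -(s_cell[xs, ys] + extra) / H if H != 0 else 0.0
    return (PairEstimate(rho, float(avar), "polychoric", n, boundary, psi),
            {"tau_x": tau_x, "tau_y": tau_y})


def polyserial_corr(x, y, ky: int | None = None,
                    compute_if: bool = True) -> tuple[PairEstimate, dict]:
    """Two-stage polyserial correlation between continuous x and ordinal y.

    x is standardized by its pairwise-complete moments; thresholds come from
    y's margins; rho maximizes the conditional likelihood of y given x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = ~(np.isnan(x) | np.isnan(y))
    n = int(m.sum())
    if n < MIN_PAIR_N:
        raise InsufficientDataError(f"pairwise n={n} below floor {MIN_PAIR_N}")
    xs = x[m]
    ys = y[m].astype(int)
    mu, sigma = xs.mean(), xs.std()
    if sigma == 0:
        raise DegenerateInputError("zero variance in continuous column")
    tau = estimate_thresholds(ys, ky, name="y")
    cuts = np.concatenate(([-np.inf], tau, [np.inf]))
    up_idx = ys + 1

    def mean_score(rho, mu_, sigma_, tau_):
        z = (xs - mu_) / sigma_
        c = np.concatenate(([-np.inf], tau_, [np.inf]))
        s = np.sqrt(1 - rho * rho)
        hi = (c[up_idx] - rho * z) / s
        lo = (c[ys] - rho * z) / s
        p = np.maximum(ndtr(hi) - ndtr(lo), 1e-300)
        # d/d rho of the category probability
        with np.errstate(invalid="ignore"):
            dhi = np.nan_to_num(
                norm.pdf(hi) * (-z * s + (c[up_idx] - rho * z) * rho / s)
                / (1 - rho * rho), nan=0.0)
            dlo = np.nan_to_num(
                norm.pdf(lo) * (-z * s + (c[ys] - rho * z) * rho / s)
                / (1 - rho * rho), nan=0.0)
        return (dhi - dlo) / p

    def nll(rho):
        z = (xs - mu) / sigma
        s = np.sqrt(1 - rho * rho)
        hi = (cuts[up_idx] - rho * z) / s
        lo = (cuts[ys] - rho * z) / s
        p = np.maximum(ndtr(hi) - ndtr(lo), 1e-300)
        return -np.sum(np.log(p)) + 1e-10 * rho ** 2

    lim = 1.0 - BOUNDARY_EPS
    res = minimize_scalar(nll, bounds=(-lim, lim), method="bounded",
                          options={"xatol": 1e-10})
    rho, boundary = _finish(res.x)

    h = 1e-4
    d2 = (nll(min(rho + h, lim)) - 2 * nll(rho) + nll(max(rho - h, -lim))) / h ** 2
    avar = 1.0 / d2 if d2 > 0 else (1 - rho * rho) ** 2 / n

    psi = None
    if compute_if:
        eps = 1e-5
        s0 = mean_score(rho, mu, sigma, tau)
        rp, rm = min(rho + eps, lim), max(rho - eps, -lim)
        H = (mean_score(rp, mu, sigma, tau).mean()
             - mean_score(rm, mu, sigma, tau).mean()) / (rp - rm)
        extra = np.zeros(n)
        # nuisance: mean and sd of x
        e_mu = sigma * 1e-4
        Jmu = (mean_score(rho, mu + e_mu, sigma, tau).mean()
               - mean_score(rho, mu - e_mu, sigma, tau).mean()) / (2 * e_mu)
        extra += Jmu * (xs - mu)
        e_s = sigma * 1e-4
        Jsg = (mean_score(rho, mu, sigma + e_s, tau).mean()
               - mean_score(rho, mu, sigma - e_s, tau).mean()) / (2 * e_s)
        extra += Jsg * ((xs - mu) ** 2 - sigma ** 2) / (2 * sigma)
        # nuisance: thresholds
        cum = np.cumsum(np.bincount(ys, minlength=len(tau) + 1))[:-1] / n
        for j in range(len(tau)):
            tp = tau.copy(); tp[j] += 1e-4
            tm = tau.copy(); tm[j] -= 1e-4
            J = (mean_score(rho, mu, sigma, tp).mean()
                 - mean_score(rho, mu, sigma, tm).mean()) / 2e-4
            if_tau = ((ys <= j).astype(float) - cum[j]) / norm.pdf(tau[j])
            extra += J * if_tau
        psi = np.full(x.shape, np.nan)
        psi[m] = -(s0 + extra) / H if H != 0 else 0.0
    return (PairEstimate(rho, float(avar), "polyserial", n, boundary, psi),
            {"tau": tau})


# ---------------------------------------------------------------------------
# mixed matrix
# ---------------------------------------------------------------------------

@dataclass
class MixedCorrelationMatrix:
    variables: list[str]
    estimates: np.ndarray                  # symmetric, unit diagonal
    pair_type: dict[tuple[str, str], str]
    thresholds: dict[str, np.ndarray]      # per categorical variable
    pair_n: np.ndarray                     # symmetric integer matrix
    asymptotic_variances: np.ndarray       # per-pair variance (DWLS weights)
    gamma: np.ndarray | None = None        # full asympt. cov of vech estimates
    boundary_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        return self.variables.index(name)

    def tri_indices(self):
        return np.triu_indices(self.p, k=1)

    def vech(self) -> np.ndarray:
        """Unique off-diagonal correlations in row-major upper-triangle order."""
        i, j = self.tri_indices()
        return self.estimates[i, j]

    def vech_avar(self) -> np.ndarray:
        i, j = self.tri_indices()
        return self.asymptotic_variances[i, j]

    def submatrix(self, names: list[str]) -> "MixedCorrelationMatrix":
        idx = [self.index(n) for n in names]
        sub_i, sub_j = np.triu_indices(self.p, k=1)
        # map of full vech positions
        pos = {(min(a, b), max(a, b)): t for t, (a, b) in enumerate(zip(sub_i, sub_j))}
        keep = [pos[(min(a, b), max(a, b))]
                for ii, a in enumerate(idx) for b in idx[ii + 1:]]
        g = None
        if self.gamma is not None:
            g = self.gamma[np.ix_(keep, keep)]
        return MixedCorrelationMatrix(
            variables=list(names),
            estimates=self.estimates[np.ix_(idx, idx)],
            pair_type={k: v for k, v in self.pair_type.items()
                       if k[0] in names and k[1] in names},
            thresholds={k: v for k, v in self.thresholds.items() if k in names},
            pair_n=self.pair_n[np.ix_(idx, idx)],
            asymptotic_variances=self.asymptotic_variances[np.ix_(idx, idx)],
            gamma=g,
            boundary_pairs=[pr for pr in self.boundary_pairs
                            if pr[0] in names and pr[1] in names],
        )

    def to_csv(self, prefix: str) -> None:
        """Write a labeled correlation CSV and a JSON sidecar of metadata."""
        pd.DataFrame(self.estimates, index=self.variables,
                     columns=self.variables).to_csv(f"{prefix}_corr.csv")
        meta = {
            "variables": self.variables,
            "pair_type": {f"{a}|{b}": t for (a, b), t in self.pair_type.items()},
            "thresholds": {k: list(map(float, v)) for k, v in self.thresholds.items()},
            "pair_n": self.pair_n.tolist(),
            "asymptotic_variances": self.asymptotic_variances.tolist(),
        }
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)


def mixed_matrix(table, schema: VariableSchema, variables: list[str],
                 min_pair_n: int = MIN_PAIR_N,
                 compute_gamma: bool = True) -> MixedCorrelationMatrix:
    """Pairwise mixed correlation matrix over pairwise-complete observations.

    `table` is a CohortTable or DataFrame.  Dispatches per pair on the
    declared measurement types; records pair sample sizes, thresholds,
    asymptotic variances and (optionally) the full asymptotic covariance of
    the stacked estimates via per-observation influence functions.
    """
    df = table.df if hasattr(table, "df") else table
    for v in variables:
        if v not in df.columns or v not in schema:
            raise KeyError(f"variable {v!r} missing from table or schema")
    p = len(variables)
    cols = {v: df[v].to_numpy(dtype=float) for v in variables}
    n_rows = len(df)

    R = np.eye(p)
    W = np.zeros((p, p))
    N = np.full((p, p), n_rows, dtype=int)
    pair_type: dict[tuple[str, str], str] = {}
    thresholds: dict[str, np.ndarray] = {}
    boundary: list[tuple[str, str]] = []
    tri = np.triu_indices(p, k=1)
    n_mom = len(tri[0])
    Psi = np.full((n_rows, n_mom), np.nan) if compute_gamma else None

    for v in variables:
        d = schema[v]
        if d.categorical:
            thresholds[v] = estimate_thresholds(cols[v], d.k, name=v)

    for t, (i, j) in enumerate(zip(*tri)):
        vi, vj = variables[i], variables[j]
        di, dj = schema[vi], schema[vj]
        try:
            if not di.categorical and not dj.categorical:
                est = pearson_corr(cols[vi], cols[vj])
            elif di.categorical and dj.categorical:
                est, _ = polychoric_corr(cols[vi], cols[vj], di.k, dj.k,
                                         compute_if=compute_gamma)
            else:
                if di.categorical:
                    est, _ = polyserial_corr(cols[vj], cols[vi], di.k,
                                             compute_if=compute_gamma)
                else:
                    est, _ = polyserial_corr(cols[vi], cols[vj], dj.k,
                                             compute_if=compute_gamma)
        except InsufficientDataError as exc:
            raise InsufficientDataError(f"pair ({vi}, {vj}): {exc}") from exc
        if est.n < min_pair_n:
            raise InsufficientDataError(
                f"pair ({vi}, {vj}): n={est.n} below floor {min_pair_n}")
        R[i, j] = R[j, i] = est.rho
        W[i, j] = W[j, i] = est.avar
        N[i, j] = N[j, i] = est.n
        pair_type[(vi, vj)] = est.pair_type
        if est.boundary:
            boundary.append((vi, vj))
        if compute_gamma and est.psi is not None:
            Psi[:, t] = est.psi

    gamma = None
    if compute_gamma:
        Z = np.nan_to_num(Psi, nan=0.0)
        counts = np.array([N[a, b] for a, b in zip(*tri)], dtype=float)
        gamma = (Z.T @ Z) / np.outer(counts, counts)
    return MixedCorrelationMatrix(list(variables), R, pair_type, thresholds,
                                  N, W, gamma, boundary)
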