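"""Observed-variable path analysis (recursive structural equation models).

The engine fits a recursive system of linear equations among observed
variables by maximum-likelihood covariance-structure estimation.  With
path-coefficient matrix A (A[outcome, predictor]) and Psi holding residual
variances (endogenous diagonal) plus free exogenous (co)variances, the
model-implied covariance is

    Sigma(theta) = (I - A)^-1 Psi (I - A)^-T

and the ML discrepancy against the sample covariance S of n rows is

    F_ML(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p .

chi^2 = (N - 1) F_ML at the minimum (Wishart convention; N F_ML available
via ``chi2_scale="N"``).  For recursive models the ML path estimates
coincide with equation-wise ordinary least squares, which supplies the
warm start; a quasi-Newton polish with the analytic gradient

    dF/dtheta = tr[ Sigma^-1 (Sigma - S) Sigma^-1 dSigma/dtheta ]

then certifies the optimum (gradient sup-norm < 1e-8).

Effects decompose as direct = A, total = (I - A)^-1 - I (sum over all
directed paths of products of coefficients), indirect = total - direct.
Uncertainty comes from a nonparametric row-resampling bootstrap, because
indirect effects are products of coefficients and their sampling
distribution is not well approximated by information-matrix Wald SEs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats


class ModelSpecError(ValueError):
    """Raised for ill-formed path-model specifications."""


class FitError(RuntimeError):
    """Raised when ML estimation cannot be completed."""


# ---------------------------------------------------------------------------
# data standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizedMatrix:
    """z-scored data matrix (column mean 0, sd 1 with n-1 denominator).

    Binary columns (e.g. the aquatic indicator) are standardized like any
    other numeric column, matching the treatment of binary variables in a
    covariance-structure SEM.  Original means/sds are retained for
    back-transformation.
    """

    columns: tuple[str, ...]
    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))


def standardize(
    table: pd.DataFrame | Mapping[str, Sequence[float]],
    columns: Sequence[str] | None = None,
) -> StandardizedMatrix:
    """z-score the selected columns: subtract the sample mean, divide by
    the sample standard deviation (n-1 denominator)."""
    df = pd.DataFrame(table)
    if columns is None:
        columns = list(df.columns)
    X = df.loc[:, list(columns)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError(f"need at least 3 rows to standardize, got {X.shape[0]}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(columns, sds):
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {name!r} has zero variance")
    return StandardizedMatrix(
        columns=tuple(columns),
        values=(X - means) / sds,
        means=means,
        sds=sds,
    )


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathModelSpec:
    """A recursive system of linear equations among observed variables.

    ``equations`` maps each endogenous outcome to its predictor tuple;
    ``exogenous`` variables appear in no equation and get free variances
    and pairwise covariances.  ``covariates`` flags abiotic explanatory
    variables: model comparison allows candidate variable sets to differ
    only in these.
    """

    variables: tuple[str, ...]
    equations: tuple[tuple[str, tuple[str, ...]], ...]
    exogenous: tuple[str, ...]
    covariates: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        outcomes = [o for o, _ in self.equations]
        if len(set(outcomes)) != len(outcomes):
            dup = sorted({o for o in outcomes if outcomes.count(o) > 1})
            raise ModelSpecError(f"repeated outcome(s): {dup}")
        known = set(self.variables)
        for o, preds in self.equations:
            missing = ({o} | set(preds)) - known
            if missing:
                raise ModelSpecError(f"equation for {o!r} uses unknown {sorted(missing)}")
            if o in preds:
                raise ModelSpecError(f"{o!r} predicts itself")
        if set(self.exogenous) & set(outcomes):
            raise ModelSpecError("exogenous variable appears as an outcome")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for o, preds in self.equations:
            g.add_edges_from((pr, o) for pr in preds)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise ModelSpecError(f"model is not recursive; cycle: {path}")

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(o for o, _ in self.equations)

    @property
    def n_free_parameters(self) -> int:
        n_exog = len(self.exogenous)
        return (
            sum(len(preds) for _, preds in self.equations)
            + len(self.equations)
            + n_exog
            + n_exog * (n_exog - 1) // 2
        )

    @property
    def df(self) -> int:
        d = self.p * (self.p + 1) // 2 - self.n_free_parameters
        if d < 0:
            raise ModelSpecError(f"negative degrees of freedom ({d})")
        return d


def parse_model_spec(text: str, covariates: Iterable[str] = ()) -> PathModelSpec:
    """Parse a model from ``outcome ~ pred1 + pred2`` lines ('#' comments).

    Variable order follows first appearance; exogenous variables are those
    never appearing as an outcome.
    """
    variables: dict[str, None] = {}
    equations: list[tuple[str, tuple[str, ...]]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~" not in line:
            raise ModelSpecError(f"line {lineno}: expected 'outcome ~ predictors'")
        lhs, rhs = line.split("~", 1)
        outcome = lhs.strip()
        preds = tuple(pr.strip() for pr in rhs.split("+") if pr.strip())
        if not outcome or not preds:
            raise ModelSpecError(f"line {lineno}: empty outcome or predictor list")
        variables.setdefault(outcome)
        for pr in preds:
            variables.setdefault(pr)
        equations.append((outcome, preds))
    if not equations:
        raise ModelSpecError("no equations found")
    outcomes = {o for o, _ in equations}
    exogenous = tuple(v for v in variables if v not in outcomes)
    return PathModelSpec(
        variables=tuple(variables),
        equations=tuple(equations),
        exogenous=exogenous,
        covariates=frozenset(covariates),
    )


def saturated_spec(variables: Sequence[str]) -> PathModelSpec:
    """Fully recursive spec in the given causal order: every variable is
    regressed on all earlier ones (df = 0)."""
    variables = tuple(variables)
    equations = tuple(
        (v, tuple(variables[:i])) for i, v in enumerate(variables) if i > 0
    )
    return PathModelSpec(
        variables=variables, equations=equations, exogenous=(variables[0],)
    )


# ---------------------------------------------------------------------------
# parameter layout and implied covariance
# ---------------------------------------------------------------------------

class _Layout:
    """Index bookkeeping between the flat parameter vector and (A, Psi)."""

    def __init__(self, spec: PathModelSpec):
        self.spec = spec
        self.idx = {v: i for i, v in enumerate(spec.variables)}
        self.paths: list[tuple[int, int]] = []  # (outcome idx, predictor idx)
        for o, preds in spec.equations:
            for pr in preds:
                self.paths.append((self.idx[o], self.idx[pr]))
        self.endo = [self.idx[o] for o, _ in spec.equations]
        self.exog = [self.idx[v] for v in spec.exogenous]
        self.exog_pairs = list(itertools.combinations(self.exog, 2))
        self.n_params = (
            len(self.paths) + len(self.endo) + len(self.exog) + len(self.exog_pairs)
        )
        assert self.n_params == spec.n_free_parameters

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.spec.p
        A = np.zeros((p, p))
        Psi = np.zeros((p, p))
        k = 0
        for (i, j) in self.paths:
            A[i, j] = theta[k]
            k += 1
        for i in self.endo:
            Psi[i, i] = theta[k]
            k += 1
        for i in self.exog:
            Psi[i, i] = theta[k]
            k += 1
        for (i, j) in self.exog_pairs:
            Psi[i, j] = Psi[j, i] = theta[k]
            k += 1
        return A, Psi

    def pack(self, A: np.ndarray, Psi: np.ndarray) -> np.ndarray:
        parts = [A[i, j] for (i, j) in self.paths]
        parts += [Psi[i, i] for i in self.endo]
        parts += [Psi[i, i] for i in self.exog]
        parts += [Psi[i, j] for (i, j) in self.exog_pairs]
        return np.array(parts)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = [(None, None)] * len(self.paths)
        b += [(1e-10, None)] * (len(self.endo) + len(self.exog))
        b += [(None, None)] * len(self.exog_pairs)
        return b


def implied_covariance(spec: PathModelSpec, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta) = (I - A)^-1 Psi (I - A)^-T, symmetric by construction."""
    layout = _Layout(spec)
    A, Psi = layout.unpack(np.asarray(theta, dtype=float))
    return _implied(A, Psi)[0]


def _implied(A: np.ndarray, Psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = A.shape[0]
    ImA = np.eye(p) - A
    if abs(np.linalg.det(ImA)) < 1e-300:
        raise FitError("(I - A) is singular")  # cannot occur for acyclic A
    B = np.linalg.inv(ImA)
    Sigma = B @ Psi @ B.T
    return (Sigma + Sigma.T) / 2.0, B


def _fml_and_grad(
    layout: _Layout, theta: np.ndarray, S: np.ndarray, logdet_S: float
) -> tuple[float, np.ndarray]:
    A, Psi = layout.unpack(theta)
    Sigma, B = _implied(A, Psi)
    sign, logdet_Sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    Sigma_inv = np.linalg.inv(Sigma)
    p = S.shape[0]
    F = logdet_Sigma + float(np.trace(S @ Sigma_inv)) - logdet_S - p
    # dF = tr(M dSigma), M = Sigma^-1 (Sigma - S) Sigma^-1
    M = Sigma_inv @ (Sigma - S) @ Sigma_inv
    gA = 2.0 * (B.T @ M @ Sigma)          # gradient wrt A entries
    gP = B.T @ M @ B                       # gradient wrt Psi entries
    grad = np.empty_like(theta)
    k = 0
    for (i, j) in layout.paths:
        grad[k] = gA[i, j]
        k += 1
    for i in layout.endo:
        grad[k] = gP[i, i]
        k += 1
    for i in layout.exog:
        grad[k] = gP[i, i]
        k += 1
    for (i, j) in layout.exog_pairs:
        grad[k] = 2.0 * gP[i, j]
        k += 1
    return F, grad


# ---------------------------------------------------------------------------
# the fit object
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    """A fitted path model: estimates, implied covariance and fit measures."""

    spec: PathModelSpec
    theta: np.ndarray
    A: np.ndarray
    Psi: np.ndarray
    Sigma_model: np.ndarray
    S_sample: np.ndarray
    N: int
    F_ML: float
    chi2: float = math.nan
    df: int = 0
    p_value: float = math.nan
    CFI: float = math.nan
    RMSEA: float = math.nan
    SRMR: float = math.nan
    GFI: float = math.nan
    AGFI: float = math.nan
    logL: float = math.nan
    AIC: float = math.nan
    R2: dict[str, float] = field(default_factory=dict)
    df_zero_conventions: bool = False
    chi2_scale: str = "N-1"

    def coefficient(self, outcome: str, predictor: str) -> float:
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        return float(self.A[idx[outcome], idx[predictor]])


def _ols_start(layout: _Layout, S: np.ndarray) -> np.ndarray:
    """Equation-wise least squares on the sample covariance; exogenous
    moments taken from S directly."""
    spec = layout.spec
    idx = layout.idx
    p = spec.p
    A = np.zeros((p, p))
    Psi = np.zeros((p, p))
    for o, preds in spec.equations:
        oi = idx[o]
        if preds:
            P = [idx[pr] for pr in preds]
            Sxx = S[np.ix_(P, P)]
            sxy = S[P, oi]
            beta = np.linalg.solve(Sxx, sxy)
            A[oi, P] = beta
            Psi[oi, oi] = max(S[oi, oi] - float(sxy @ beta), 1e-8)
        else:
            Psi[oi, oi] = S[oi, oi]
    for i in layout.exog:
        Psi[i, i] = S[i, i]
    for (i, j) in layout.exog_pairs:
        Psi[i, j] = Psi[j, i] = S[i, j]
    return layout.pack(A, Psi)


def fit_ml(
    spec: PathModelSpec,
    data: StandardizedMatrix,
    chi2_scale: str = "N-1",
    _S: np.ndarray | None = None,
) -> SemFit:
    """Maximum-likelihood fit of ``spec`` to the rows of ``data``.

    Starts at the equation-wise OLS solution (the exact ML optimum for
    recursive models) and polishes with bounded quasi-Newton; raises
    :class:`FitError` unless the gradient sup-norm falls below 1e-8.
    """
    cols = set(data.columns)
    missing = set(spec.variables) - cols
    if missing:
        raise FitError(f"data lacks model variables {sorted(missing)}")
    order = [list(data.columns).index(v) for v in spec.variables]
    X = data.values[:, order]
    n, p = X.shape
    if n <= p:
        raise FitError(f"need n > p, got n={n}, p={p}")
    S = np.cov(X, rowvar=False, ddof=1) if _S is None else _S
    S = (S + S.T) / 2.0
    if np.min(np.linalg.eigvalsh(S)) < 1e-10:
        raise FitError("sample covariance is not positive definite")
    sign, logdet_S = np.linalg.slogdet(S)

    layout = _Layout(spec)
    theta0 = _ols_start(layout, S)
    F0, g0 = _fml_and_grad(layout, theta0, S, logdet_S)
    if np.max(np.abs(g0)) < 1e-8:
        theta, F = theta0, F0
    else:
        res = optimize.minimize(
            _fml_and_grad,
            theta0,
            args=(S, logdet_S),
            jac=True,
            method="L-BFGS-B",
            bounds=layout.bounds(),
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        theta, F = res.x, float(res.fun)
        _, g = _fml_and_grad(layout, theta, S, logdet_S)
        if np.max(np.abs(g)) >= 1e-8:
            raise FitError(
                f"optimizer did not converge: F={F:.6g}, "
                f"grad sup-norm={np.max(np.abs(g)):.3g}, message={res.message!r}"
            )

    A, Psi = layout.unpack(theta)
    Sigma, _ = _implied(A, Psi)
    F = max(F, 0.0)
    idx = layout.idx
    R2 = {
        o: 1.0 - Psi[idx[o], idx[o]] / S[idx[o], idx[o]]
        for o, _pr in spec.equations
    }
    fit = SemFit(
        spec=spec, theta=theta, A=A, Psi=Psi, Sigma_model=Sigma, S_sample=S,
        N=n, F_ML=F, df=spec.df, R2=R2, chi2_scale=chi2_scale,
    )
    return fit_indices(fit)


def fit_indices(fit: SemFit, N: int | None = None) -> SemFit:
    """Complete a fit with chi^2, p, CFI, RMSEA, SRMR, GFI/AGFI, logL, AIC.

    The independence (diagonal-covariance) baseline needed by CFI has a
    closed-form ML solution: Sigma_b = diag(S), F_b = sum ln S_ii - ln|S|.
    When df = 0 the conventional values RMSEA = 0 and AGFI = 1 are
    reported and flagged via ``df_zero_conventions``.
    """
    N = fit.N if N is None else N
    S, Sigma = fit.S_sample, fit.Sigma_model
    p = S.shape[0]
    df = fit.df
    scale = (N - 1) if fit.chi2_scale == "N-1" else N
    chi2 = scale * fit.F_ML
    sign_s, logdet_S = np.linalg.slogdet(S)
    F_b = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_b = scale * F_b
    df_b = p * (p - 1) // 2

    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    CFI = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    df_zero = df == 0
    RMSEA = 0.0 if df_zero else math.sqrt(max(chi2 - df, 0.0) / (df * (N - 1)))
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    SRMR = float(np.sqrt(np.mean(resid[iu] ** 2)))
    Sigma_inv = np.linalg.inv(Sigma)
    W = Sigma_inv @ S
    GFI = 1.0 - float(np.trace((W - np.eye(p)) @ (W - np.eye(p)))) / float(
        np.trace(W @ W)
    )
    AGFI = 1.0 if df_zero else 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - GFI)
    logL = -0.5 * N * (
        p * math.log(2 * math.pi)
        + float(np.linalg.slogdet(Sigma)[1])
        + float(np.trace(S @ Sigma_inv))
    )
    AIC = -2.0 * logL + 2.0 * fit.spec.n_free_parameters
    return replace(
        fit, chi2=chi2, p_value=p_value, CFI=CFI, RMSEA=RMSEA, SRMR=SRMR,
        GFI=GFI, AGFI=AGFI, logL=logL, AIC=AIC, df_zero_conventions=df_zero,
    )


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------

def effect_matrices(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(direct, indirect, total) effect matrices, orientation
    [outcome, cause].  total = (I - A)^-1 - I equals the sum over all
    directed paths of products of path coefficients."""
    p = A.shape[0]
    total = np.linalg.inv(np.eye(p) - A) - np.eye(p)
    return A.copy(), total - A, total


def effect_decomposition(fit: SemFit) -> pd.DataFrame:
    """Standardized direct/indirect/total effect for every ordered
    (cause, outcome) pair with any nonzero effect."""
    direct, indirect, total = effect_matrices(fit.A)
    names = fit.spec.variables
    rows = []
    for ci, cause in enumerate(names):
        for oi, outcome in enumerate(names):
            if ci == oi:
                continue
            d, ind, tot = direct[oi, ci], indirect[oi, ci], total[oi, ci]
            if d == 0 and ind == 0 and tot == 0:
                continue
            rows.append(
                {"cause": cause, "outcome": outcome,
                 "direct": d, "indirect": ind, "total": tot}
            )
    return pd.DataFrame(rows, columns=["cause", "outcome", "direct", "indirect", "total"])


def bootstrap_se(
    spec: PathModelSpec,
    data: StandardizedMatrix,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nonparametric bootstrap of the effects table.

    Rows are resampled with replacement, each replicate is re-standardized
    and refit, and the SE of every direct/indirect/total effect is the
    standard deviation across replicates.  z = estimate / SE with a normal
    reference; percentile CIs are included.  More than 10% failed
    replicates aborts.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    fit = fit_ml(spec, data)
    base = effect_decomposition(fit)
    pairs = list(zip(base["cause"], base["outcome"]))
    idx = {v: i for i, v in enumerate(spec.variables)}

    draws = np.empty((B, len(pairs), 3))
    n_fail = 0
    n = data.n
    raw = data.values  # affine-invariant: re-standardizing z-scores is fine
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        Xb = raw[rows]
        sds = Xb.std(axis=0, ddof=1)
        if np.any(sds == 0):
            n_fail += 1
            draws[b] = np.nan
            continue
        zb = StandardizedMatrix(
            columns=data.columns,
            values=(Xb - Xb.mean(axis=0)) / sds,
            means=Xb.mean(axis=0),
            sds=sds,
        )
        try:
            fb = fit_ml(spec, zb)
        except FitError:
            n_fail += 1
            draws[b] = np.nan
            continue
        d, ind, tot = effect_matrices(fb.A)
        for k, (cause, outcome) in enumerate(pairs):
            oi, ci = idx[outcome], idx[cause]
            draws[b, k] = (d[oi, ci], ind[oi, ci], tot[oi, ci])

    if n_fail > 0.10 * B:
        raise FitError(f"{n_fail}/{B} bootstrap replicates failed to converge")

    out = base.copy()
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    for j, kind in enumerate(["direct", "indirect", "total"]):
        col = draws[:, :, j]
        se = np.nanstd(col, axis=0, ddof=1)
        est = base[kind].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.nan)
        pv = 2 * stats.norm.sf(np.abs(z))
        out[f"se_{kind}"] = se
        out[f"z_{kind}"] = z
        out[f"p_{kind}"] = pv
        out[f"sig_{kind}"] = pv < alpha
        out[f"ci_lo_{kind}"] = np.nanpercentile(col, lo_q, axis=0)
        out[f"ci_hi_{kind}"] = np.nanpercentile(col, hi_q, axis=0)
    return out


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

COMPARISON_COLUMNS = [
    "model", "chi2", "df", "p_value", "CFI", "RMSEA", "SRMR", "AGFI", "AIC", "dAIC",
]


def compare_models(fits: Mapping[str, SemFit]) -> pd.DataFrame:
    """Rank named fits by AIC (ascending) with dAIC = AIC - min(AIC).

    All fits must share the sample size, and their variable sets may
    differ only in declared abiotic covariates — otherwise the AICs are
    not comparable and an error is raised.
    """
    if not fits:
        raise ValueError("no fits to compare")
    items = list(fits.items())
    Ns = {f.N for _, f in items}
    if len(Ns) != 1:
        raise ValueError(f"fits have different sample sizes: {sorted(Ns)}")
    allowed = frozenset().union(*(f.spec.covariates for _, f in items))
    sets = [set(f.spec.variables) for _, f in items]
    common = set.intersection(*sets)
    for (name, f), s in zip(items, sets):
        extra = (s - common) | (common - s)
        if not extra <= allowed:
            raise ValueError(
                f"model {name!r}: variable set differs by non-covariate "
                f"columns {sorted(extra - allowed)}; AIC not comparable"
            )
    rows = [
        {
            "model": name, "chi2": f.chi2, "df": f.df, "p_value": f.p_value,
            "CFI": f.CFI, "RMSEA": f.RMSEA, "SRMR": f.SRMR, "AGFI": f.AGFI,
            "AIC": f.AIC,
        }
        for name, f in items
    ]
    table = pd.DataFrame(rows, columns=COMPARISON_COLUMNS[:-1])
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    table = table.sort_values(["AIC", "model"], kind="mergesort").reset_index(drop=True)
    return table[COMPARISON_COLUMNS]
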