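"""Covariance-based structural equation modelling with composite variables.

A small maximum-likelihood SEM engine for recursive path models among
observed variables, sufficient for analysing drivers of wood
production: directed paths, free residual/exogenous (co)variances, and
*composite* variables — deterministic weighted combinations of observed
variables that transmit a single structural coefficient.  Basal area is
the motivating composite: on the log scale it is exactly
2*log(QMD) + log(n_stems) + const, so its "loadings" are fixed by
algebra rather than estimated, and the composite contributes one free
parameter (its effect on the outcome), not a latent variable.

Estimation minimizes the Wishart maximum-likelihood discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

with Sigma(theta) = (I-B)^-1 Psi (I-B)^-T assembled from the path
matrix B and the residual/exogenous covariance matrix Psi.  The model
chi-square is (N-1) * F_min; RMSEA, CFI (against the independence
baseline) and SRMR are computed from it.  Standard errors come from the
inverse observed information (numerical Hessian of the discrepancy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class SEMError(RuntimeError):
    pass


@dataclass
class Path:
    src: str           # variable or composite name
    dst: str
    free: bool = True
    value: float | None = None   # fixed coefficient when free=False


@dataclass
class CovEdge:
    a: str
    b: str


@dataclass
class Composite:
    """Weighted combination of observed variables acting as a single cause.

    With ``free_loadings`` the first component's weight stays fixed for
    identification and the rest are estimated; by default all weights are
    fixed constants (an exact algebraic composite).
    """
    name: str
    weights: dict[str, float]
    free_loadings: bool = False


@dataclass
class SEMSpec:
    variables: list[str]
    transforms: dict[str, str] = field(default_factory=dict)  # "log"|"none"
    paths: list[Path] = field(default_factory=list)
    covariances: list[CovEdge] = field(default_factory=list)
    composites: dict[str, Composite] = field(default_factory=dict)

    def model_var(self, v: str) -> str:
        return f"log_{v}" if self.transforms.get(v) == "log" else v

    @property
    def model_variables(self) -> list[str]:
        return [self.model_var(v) for v in self.variables]

    def validate(self) -> None:
        names = set(self.variables) | set(self.composites)
        for p in self.paths:
            if p.src not in names or p.dst not in self.variables:
                raise SEMError(f"path {p.src}->{p.dst}: undeclared endpoint")
            if p.dst in self.composites:
                raise SEMError("composites cannot be path outcomes")
        for c in self.covariances:
            if c.a not in self.variables or c.b not in self.variables:
                raise SEMError(f"covariance {c.a}<->{c.b}: undeclared variable")
        for comp in self.composites.values():
            for v in comp.weights:
                if v not in self.variables:
                    raise SEMError(f"composite {comp.name}: unknown {v}")
        # acyclicity of the expanded directed graph
        edges = {v: set() for v in self.variables}
        for p in self.paths:
            srcs = (self.composites[p.src].weights if p.src in self.composites
                    else {p.src: 1.0})
            for s in srcs:
                edges[s].add(p.dst)
        seen: dict[str, int] = {}

        def visit(v: str) -> None:
            seen[v] = 1
            for w in edges[v]:
                if seen.get(w) == 1:
                    raise SEMError("directed path graph contains a cycle")
                if w not in seen:
                    visit(w)
            seen[v] = 2

        for v in self.variables:
            if v not in seen:
                visit(v)

    # -- bookkeeping -------------------------------------------------------
    def endogenous(self) -> list[str]:
        return [v for v in self.variables
                if any(p.dst == v for p in self.paths)]

    def exogenous(self) -> list[str]:
        endo = set(self.endogenous())
        return [v for v in self.variables if v not in endo]


def apply_transforms(data: pd.DataFrame, spec: SEMSpec) -> pd.DataFrame:
    """Return the analysis table: transformed columns, model names,
    complete cases only (listwise deletion)."""
    out = {}
    for v in spec.variables:
        col = pd.to_numeric(data[v], errors="coerce")
        if spec.transforms.get(v) == "log":
            col = np.log(col.where(col > 0))
        out[spec.model_var(v)] = col
    return pd.DataFrame(out).dropna()


# ---------------------------------------------------------------------------
# Parameterization

class _ParamMap:
    """Maps a flat parameter vector to (B, Psi) and back."""

    def __init__(self, spec: SEMSpec):
        spec.validate()
        self.spec = spec
        self.vars = spec.variables
        self.idx = {v: i for i, v in enumerate(self.vars)}
        p = len(self.vars)
        endo = set(spec.endogenous())
        self.names: list[str] = []
        self.free_paths = [pa for pa in spec.paths if pa.free]
        for pa in self.free_paths:
            self.names.append(f"{pa.src}->{pa.dst}")
        self.free_loadings: list[tuple[str, str]] = []
        for comp in spec.composites.values():
            if comp.free_loadings:
                for v in list(comp.weights)[1:]:
                    self.free_loadings.append((comp.name, v))
                    self.names.append(f"{comp.name}={v}")
        for v in self.vars:
            self.names.append(f"var({v})")
        # free covariances: declared edges plus all exogenous pairs
        exo = spec.exogenous()
        pairs = {tuple(sorted((c.a, c.b))) for c in spec.covariances}
        for i, a in enumerate(exo):
            for b in exo[i + 1:]:
                pairs.add(tuple(sorted((a, b))))
        self.cov_pairs = sorted(pairs)
        for a, b in self.cov_pairs:
            self.names.append(f"cov({a},{b})")
        self.n_params = len(self.names)
        self.p = p
        self.df = p * (p + 1) // 2 - self.n_params

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        B = np.zeros((p, p))
        k = 0
        path_vals = {}
        for pa in self.free_paths:
            path_vals[(pa.src, pa.dst)] = theta[k]
            k += 1
        loading_vals = dict.fromkeys(self.free_loadings)
        for key in self.free_loadings:
            loading_vals[key] = theta[k]
            k += 1
        for pa in self.spec.paths:
            beta = (path_vals[(pa.src, pa.dst)] if pa.free else pa.value)
            j = self.idx[pa.dst]
            if pa.src in self.spec.composites:
                comp = self.spec.composites[pa.src]
                for m, (v, w) in enumerate(comp.weights.items()):
                    if comp.free_loadings and m > 0:
                        w = loading_vals[(comp.name, v)]
                    B[j, self.idx[v]] += beta * w
            else:
                B[j, self.idx[pa.src]] += beta
        Psi = np.zeros((p, p))
        for v in self.vars:
            Psi[self.idx[v], self.idx[v]] = theta[k]
            k += 1
        for a, b in self.cov_pairs:
            Psi[self.idx[a], self.idx[b]] = theta[k]
            Psi[self.idx[b], self.idx[a]] = theta[k]
            k += 1
        return B, Psi

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        B, Psi = self.matrices(theta)
        inv = np.linalg.inv(np.eye(self.p) - B)
        return inv @ Psi @ inv.T


def _discrepancy(Sigma: np.ndarray, S: np.ndarray, logdet_S: float) -> float:
    # Cholesky doubles as the positive-definiteness check (a determinant
    # sign test would accept matrices with paired negative eigenvalues)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    y = np.linalg.solve(L, S)
    tr = float(np.trace(np.linalg.solve(L.T, y)))
    return logdet + tr - logdet_S - S.shape[0]


# ---------------------------------------------------------------------------
# Fit container

@dataclass
class SEMFit:
    spec: SEMSpec
    param_names: list[str]
    estimates: np.ndarray
    se: np.ndarray | None
    S: np.ndarray
    Sigma: np.ndarray
    N: int
    F_min: float
    chi2: float
    df: int
    p_value: float
    chi2_baseline: float
    df_baseline: int
    rmsea: float = float("nan")
    cfi: float = float("nan")
    srmr: float = float("nan")
    std_paths: dict[str, float] = field(default_factory=dict)
    r2: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def std_error(self, name: str) -> float | None:
        if self.se is None:
            return None
        return float(self.se[self.param_names.index(name)])

    def confint(self, name: str, level: float = 0.95
                ) -> tuple[float, float]:
        se = self.std_error(name)
        if se is None or not np.isfinite(se):
            raise SEMError(f"no standard error for {name}")
        z = stats.norm.ppf(0.5 + level / 2)
        est = self.estimate(name)
        return est - z * se, est + z * se

    def to_dict(self) -> dict:
        return {
            "N": self.N, "F_min": self.F_min, "chi2": self.chi2,
            "df": self.df, "p_value": self.p_value, "rmsea": self.rmsea,
            "cfi": self.cfi, "srmr": self.srmr,
            "estimates": dict(zip(self.param_names, self.estimates.tolist())),
            "se": (dict(zip(self.param_names, self.se.tolist()))
                   if self.se is not None else None),
            "std_paths": self.std_paths, "r2": self.r2,
            "p_values": self.p_values,
        }


# ---------------------------------------------------------------------------
# Estimation

def _ols_start(pm: _ParamMap, S: np.ndarray) -> np.ndarray:
    """Per-equation least-squares starting values computed from S alone."""
    spec, idx = pm.spec, pm.idx
    theta = np.zeros(pm.n_params)
    # predictor set per endogenous variable, composites expanded
    preds: dict[str, list[tuple[str, dict[str, float]]]] = {}
    for pa in spec.paths:
        w = (dict(spec.composites[pa.src].weights)
             if pa.src in spec.composites else {pa.src: 1.0})
        preds.setdefault(pa.dst, []).append((f"{pa.src}->{pa.dst}", w))
    resid_var = {v: S[idx[v], idx[v]] for v in spec.variables}
    for dst, plist in preds.items():
        k = len(plist)
        A = np.zeros((k, k))
        b = np.zeros(k)
        for i, (_, wi) in enumerate(plist):
            b[i] = sum(w * S[idx[v], idx[dst]] for v, w in wi.items())
            for j, (_, wj) in enumerate(plist):
                A[i, j] = sum(wi[v1] * wj[v2] * S[idx[v1], idx[v2]]
                              for v1 in wi for v2 in wj)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.zeros(k)
        rv = S[idx[dst], idx[dst]] - float(beta @ b)
        resid_var[dst] = max(rv, 0.05 * S[idx[dst], idx[dst]])
        for (name, _), bb in zip(plist, beta):
            if name in pm.names:
                theta[pm.names.index(name)] = bb
    for v in spec.variables:
        theta[pm.names.index(f"var({v})")] = resid_var[v]
    exo = set(spec.exogenous())
    for a, b_ in pm.cov_pairs:
        if a in exo and b_ in exo:
            theta[pm.names.index(f"cov({a},{b_})")] = S[idx[a], idx[b_]]
    for comp in spec.composites.values():
        if comp.free_loadings:
            for v in list(comp.weights)[1:]:
                theta[pm.names.index(f"{comp.name}={v}")] = comp.weights[v]
    return theta


def fit_ml(data: pd.DataFrame, spec: SEMSpec, seed: int = 0,
           compute_se: bool = True, n_convention: str = "n-1") -> SEMFit:
    """Fit the path model by maximum likelihood.

    ``data`` holds the raw observed columns; transforms declared in the
    spec are applied and incomplete rows dropped before the sample
    covariance is formed.  chi2 uses the (N-1) convention by default
    (``n_convention="n"`` switches to N * F_min).  Raises
    :class:`SEMError` for non-positive-definite sample covariance or a
    non-converged optimizer.
    """
    table = apply_transforms(data, spec)
    N = len(table)
    pm = _ParamMap(spec)
    if N <= pm.p:
        raise SEMError(f"N={N} too small for {pm.p} observed variables")
    X = table[spec.model_variables].to_numpy()
    S = np.cov(X, rowvar=False, ddof=1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise SEMError(
            "sample covariance is not positive definite; check for "
            "linearly dependent or constant variables")
    if pm.df < 0:
        raise SEMError(f"negative degrees of freedom ({pm.df})")

    def objective(theta):
        return _discrepancy(pm.implied_cov(theta), S, logdet_S)

    rng = np.random.default_rng(seed)
    start0 = _ols_start(pm, S)
    starts = [start0]
    for _ in range(2):  # multi-start insurance against local minima
        jitter = start0 * (1 + 0.1 * rng.standard_normal(len(start0)))
        starts.append(jitter)
    best = None
    for s0 in starts:
        res = optimize.minimize(objective, s0, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14,
                                         "maxiter": 20000, "maxfev": 40000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise SEMError(f"SEM optimization failed: {best}")
    theta = best.x
    F_min = max(float(best.fun), 0.0)
    n_eff = N - 1 if n_convention == "n-1" else N
    chi2 = n_eff * F_min
    df = pm.df
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # independence baseline: diagonal Sigma at its MLE (variances = s_ii)
    F_b = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_b = n_eff * F_b
    df_b = pm.p * (pm.p - 1) // 2

    se = None
    if compute_se:
        se = _standard_errors(objective, theta, N)

    fit = SEMFit(spec=spec, param_names=pm.names, estimates=theta, se=se,
                 S=S, Sigma=pm.implied_cov(theta), N=N, F_min=F_min,
                 chi2=chi2, df=df, p_value=p_value,
                 chi2_baseline=chi2_b, df_baseline=df_b)
    fit.rmsea, fit.cfi, fit.srmr = fit_indices(fit)
    standardize_and_r2(fit)
    return fit


def _standard_errors(objective, theta: np.ndarray, N: int) -> np.ndarray:
    """Delta-method SEs from the numerical Hessian of the discrepancy:
    cov(theta) = 2/(N-1) * H^-1."""
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-4 * np.maximum(np.abs(theta), 0.1)
    f0 = objective(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (objective(theta + ei) - 2 * f0
                       + objective(theta - ei)) / h[i] ** 2
            else:
                val = (objective(theta + ei + ej) - objective(theta + ei - ej)
                       - objective(theta - ei + ej)
                       + objective(theta - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    try:
        cov = 2.0 / (N - 1) * np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


# ---------------------------------------------------------------------------
# Fit indices, standardization

def fit_indices(fit: SEMFit) -> tuple[float, float, float]:
    """(RMSEA, CFI, SRMR) from the fitted and baseline chi-squares.

    RMSEA = sqrt(max(chi2-df, 0) / (df*(N-1))), 0 when df = 0;
    CFI compares excess chi-square against the independence baseline;
    SRMR is the RMS difference between sample and implied correlations
    over the unique lower triangle (diagonal included).
    """
    chi2, df, N = fit.chi2, fit.df, fit.N
    rmsea = 0.0 if df == 0 else math.sqrt(max(chi2 - df, 0.0) / (df * (N - 1)))
    denom = max(fit.chi2_baseline - fit.df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    S, Sig = fit.S, fit.Sigma
    ds = np.sqrt(np.diag(S))
    dm = np.sqrt(np.diag(Sig))
    Rs = S / np.outer(ds, ds)
    Rm = Sig / np.outer(dm, dm)
    iu = np.triu_indices(len(ds))
    srmr = float(np.sqrt(np.mean((Rs[iu] - Rm[iu]) ** 2)))
    return rmsea, cfi, srmr


def standardize_and_r2(fit: SEMFit) -> tuple[dict[str, float], dict[str, float]]:
    """Standardized path coefficients, R^2 per endogenous variable and
    Wald p-values; results are stored on the fit and returned.

    Each path coefficient is rescaled by SD(source)/SD(outcome) using
    model-implied variances; a composite's SD comes from the implied
    covariance of its components, and its fixed loadings are reported in
    standardized form too (their p-values are not applicable and are
    omitted).  R^2 = 1 - residual variance / implied variance.
    """
    spec = fit.spec
    pm = _ParamMap(spec)
    idx = pm.idx
    Sig = fit.Sigma
    B, Psi = pm.matrices(fit.estimates)

    def sd_of(name: str) -> float:
        if name in spec.composites:
            comp = spec.composites[name]
            w = np.array(list(comp.weights.values()))
            ii = [idx[v] for v in comp.weights]
            return math.sqrt(float(w @ Sig[np.ix_(ii, ii)] @ w))
        return math.sqrt(Sig[idx[name], idx[name]])

    std: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for pa in spec.paths:
        name = f"{pa.src}->{pa.dst}"
        beta = (fit.estimate(name) if pa.free else pa.value)
        std[name] = beta * sd_of(pa.src) / sd_of(pa.dst)
        if pa.free and fit.se is not None:
            se = fit.std_error(name)
            if se and np.isfinite(se) and se > 0:
                pvals[name] = 2 * float(stats.norm.sf(abs(beta / se)))
    for comp in spec.composites.values():
        for m, (v, w) in enumerate(comp.weights.items()):
            if comp.free_loadings and m > 0:
                w = fit.estimate(f"{comp.name}={v}")
            std[f"{v}->{comp.name}"] = w * sd_of(v) / sd_of(comp.name)
    r2: dict[str, float] = {}
    for v in spec.endogenous():
        i = idx[v]
        r2[v] = 1.0 - Psi[i, i] / Sig[i, i]
    fit.std_paths, fit.r2, fit.p_values = std, r2, pvals
    return std, r2


# ---------------------------------------------------------------------------
# The default drivers-of-production model

#: raw column names expected in the SEM input table
AWP, QMD, NSTEMS, DIVERSITY, SOILP, LOGGED, SLOPE = (
    "AWP", "QMD", "n_stems", "diversity", "soilP", "logged", "slope")


def build_default_spec(free_loadings: bool = False) -> SEMSpec:
    """The drivers-of-wood-production path model.

    AWP is driven by basal area (a composite of log QMD and log stem
    density with algebra-fixed weights 2 and 1), tree diversity, and
    soil P; diversity responds to stem density, soil P and logging; QMD
    responds to logging and slope; stem density and QMD covary.  AWP,
    QMD and n_stems are log-transformed; the ordinal soil class and the
    logging flag enter as numeric covariates.
    """
    spec = SEMSpec(
        variables=[AWP, QMD, NSTEMS, DIVERSITY, SOILP, LOGGED, SLOPE],
        transforms={AWP: "log", QMD: "log", NSTEMS: "log"},
        composites={"BA": Composite(
            name="BA", weights={QMD: 2.0, NSTEMS: 1.0},
            free_loadings=free_loadings)},
        paths=[
            Path("BA", AWP),
            Path(DIVERSITY, AWP),
            Path(SOILP, AWP),
            Path(NSTEMS, DIVERSITY),
            Path(SOILP, DIVERSITY),
            Path(LOGGED, DIVERSITY),
            Path(LOGGED, QMD),
            Path(SLOPE, QMD),
        ],
        covariances=[CovEdge(NSTEMS, QMD)],
    )
    # composite weights refer to model (transformed) variables
    spec.composites["BA"].weights = {QMD: 2.0, NSTEMS: 1.0}
    spec.validate()
    return spec


def simulate_from_spec(spec: SEMSpec, params: dict[str, float], n: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw an N-row raw data table from the path model.

    ``params`` maps parameter names (as in ``_ParamMap.names``) to true
    values; unset variances default to 1 and unset paths/covariances to
    0.  Log-transformed variables are exponentiated back to the raw
    scale so the frame can be fed straight to :func:`fit_ml`.
    """
    pm = _ParamMap(spec)
    theta = np.zeros(pm.n_params)
    for i, name in enumerate(pm.names):
        if name.startswith("var("):
            theta[i] = params.get(name, 1.0)
        else:
            theta[i] = params.get(name, 0.0)
    B, Psi = pm.matrices(theta)
    # residual/exogenous draws, then propagate through the paths
    L = np.linalg.cholesky(Psi + 1e-12 * np.eye(pm.p))
    e = rng.standard_normal((n, pm.p)) @ L.T
    X = e @ np.linalg.inv(np.eye(pm.p) - B).T
    out = {}
    for j, v in enumerate(spec.variables):
        col = X[:, j]
        if spec.transforms.get(v) == "log":
            col = np.exp(col)
        out[v] = col
    return pd.DataFrame(out)
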