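"""Hierarchical source-sink structural-equation model of yield architecture.

The pinned model explains total yield (TY) through two latent constructs:
vegetative growth (VEG; indicators leaf width, leaf number, petiole
length) and rhizome sink strength (SINK), a second-order factor measured
by two first-order latents - primary-rhizome mass (F_WPR; indicators NPR
and rhizome girth) and mother-rhizome mass (F_WMR; indicators NMR and
rhizome girth).  Structural paths: VEG -> SINK, SINK -> TY, VEG -> TY.
With 7 observed variables (28 distinct covariance moments) and 19 free
parameters the model has 9 degrees of freedom.

Estimation is normal-theory maximum likelihood on the sample covariance:

    F_ML(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^-1) - p

minimized by quasi-Newton with an analytic gradient from multiple seeded
starts; chi2 = (n-1) F_min, standard errors from the inverse observed
information.  Variance parameters are unconstrained, so negative (Heywood)
residual variances can occur and are flagged rather than forbidden.
The implied-covariance computation uses the RAM form: with path matrix A
and diagonal variance matrix Psi, V = (I-A)^-1 Psi (I-A)^-T and Sigma is
the observed block of V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fieldbook import logger


@dataclass(frozen=True)
class Path:
    """A directed path src -> dst; ``value`` None means free, else fixed."""

    src: str
    dst: str
    value: float | None = None


@dataclass
class SemSpec:
    """A fixed confirmatory model: observed variables, latents, paths.

    Every variable (latent or observed) carries exactly one free variance
    parameter (exogenous variance, disturbance, or residual).
    """

    observed: list[str]
    latents: list[str]
    paths: list[Path]
    name: str = ""

    def __post_init__(self) -> None:
        self.variables = list(self.latents) + list(self.observed)
        dup = set(self.latents) & set(self.observed)
        if dup:
            raise ValueError(f"names used as both latent and observed: {sorted(dup)}")
        for p in self.paths:
            if p.src not in self.variables or p.dst not in self.variables:
                raise ValueError(f"path {p.src}->{p.dst} references unknown variable")

    @property
    def free_paths(self) -> list[Path]:
        return [p for p in self.paths if p.value is None]

    @property
    def n_free(self) -> int:
        return len(self.free_paths) + len(self.variables)


def turmeric_sem_spec(gr: str = "GPR") -> SemSpec:
    """The pinned hierarchical source-sink model (df = 9).

    ``gr`` names the rhizome-girth column (GPR in the bundled trait
    config); it cross-loads on both first-order sink factors.
    """
    return SemSpec(
        observed=["LW", "NL", "PL", "NPR", gr, "NMR", "TY"],
        latents=["VEG", "SINK", "F_WPR", "F_WMR"],
        paths=[
            Path("VEG", "LW", 1.0),
            Path("VEG", "NL"),
            Path("VEG", "PL"),
            Path("SINK", "F_WPR", 1.0),
            Path("SINK", "F_WMR"),
            Path("F_WPR", "NPR", 1.0),
            Path("F_WPR", gr),
            Path("F_WMR", "NMR", 1.0),
            Path("F_WMR", gr),
            Path("VEG", "SINK"),
            Path("SINK", "TY"),
            Path("VEG", "TY"),
        ],
        name="turmeric_source_sink",
    )


def model_df(spec: SemSpec) -> int:
    """df = p(p+1)/2 - free covariance-structure parameters (mean structure
    saturated and excluded)."""
    p = len(spec.observed)
    df = p * (p + 1) // 2 - spec.n_free
    if df < 0:
        raise ValueError(f"model not identified: {spec.n_free} free parameters "
                         f"exceed {p * (p + 1) // 2} covariance moments")
    return df


class _Ram:
    """Index bookkeeping and linear algebra for a SemSpec."""

    def __init__(self, spec: SemSpec):
        self.spec = spec
        self.vars = spec.variables
        self.idx = {v: i for i, v in enumerate(self.vars)}
        self.m = len(self.vars)
        self.obs_idx = np.array([self.idx[v] for v in spec.observed])
        self.free_edges = [(self.idx[p.dst], self.idx[p.src]) for p in spec.free_paths]
        self.fixed_edges = [(self.idx[p.dst], self.idx[p.src], p.value)
                            for p in spec.paths if p.value is not None]
        self.n_paths = len(self.free_edges)
        self.n_theta = self.n_paths + self.m
        self.param_names = ([f"{p.src}->{p.dst}" for p in spec.free_paths]
                            + [f"var({v})" for v in self.vars])

    def matrices(self, theta: np.ndarray):
        A = np.zeros((self.m, self.m))
        for (i, j), val in zip(self.free_edges, theta[:self.n_paths]):
            A[i, j] = val
        for i, j, val in self.fixed_edges:
            A[i, j] = val
        psi = theta[self.n_paths:]
        return A, psi

    def full_cov(self, theta: np.ndarray) -> np.ndarray:
        A, psi = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.m) - A)
        return B @ np.diag(psi) @ B.T

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        V = self.full_cov(theta)
        return V[np.ix_(self.obs_idx, self.obs_idx)]

    def objective_and_grad(self, theta: np.ndarray, S: np.ndarray, logdet_S: float):
        p = len(self.obs_idx)
        A, psi = self.matrices(theta)
        try:
            B = np.linalg.inv(np.eye(self.m) - A)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        V = B @ np.diag(psi) @ B.T
        Sig = V[np.ix_(self.obs_idx, self.obs_idx)]
        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet = 2 * np.log(np.diag(L)).sum()
        Sinv = np.linalg.inv(Sig)
        F = logdet - logdet_S + float(np.trace(S @ Sinv)) - p
        W = Sinv - Sinv @ S @ Sinv           # dF = tr(W dSigma)
        G = np.zeros((self.m, self.m))       # W embedded in full-variable space
        G[np.ix_(self.obs_idx, self.obs_idx)] = W
        M = B.T @ G @ B
        grad = np.empty(self.n_theta)
        VGB = V @ G @ B
        for k, (i, j) in enumerate(self.free_edges):
            grad[k] = 2.0 * VGB[j, i]
        grad[self.n_paths:] = np.diag(M)
        return F, grad


@dataclass
class SemFit:
    """ML solution: estimates, fit statistics, implied covariance, flags."""

    spec: SemSpec
    theta: pd.Series
    se: pd.Series
    z: pd.Series
    Sigma_hat: pd.DataFrame
    F_min: float
    chi2: float
    df: int
    p: float
    n: int
    converged: bool
    grad_norm: float
    n_starts: int
    heywood: list[str] = field(default_factory=list)


class SemConvergenceError(RuntimeError):
    def __init__(self, F: float, grad_norm: float):
        super().__init__(f"SEM did not converge: best F={F:.6g}, "
                         f"gradient max-norm={grad_norm:.3g}")
        self.F = F
        self.grad_norm = grad_norm


def _marker_scales(spec: SemSpec, sds: dict[str, float]) -> dict[str, float]:
    """Scale factor per variable: observed -> its sd; latent -> the scale of
    its (fixed-at-1) marker, resolved recursively for higher-order factors."""
    scale = dict(sds)
    markers = {p.src: p.dst for p in spec.paths if p.value == 1.0}
    for _ in range(len(spec.latents) + 1):
        for lat in spec.latents:
            if lat not in scale and markers.get(lat) in scale:
                scale[lat] = scale[markers[lat]]
    missing = [v for v in spec.variables if v not in scale]
    if missing:
        raise ValueError(f"no marker chain fixes the scale of: {missing}")
    return scale


def fit_ml(S: pd.DataFrame | np.ndarray, n: int, spec: SemSpec, *,
           seed: int = 0, n_starts: int = 10, compute_se: bool = True,
           grad_tol: float = 1e-6) -> SemFit:
    """Fit the model to a sample covariance matrix by maximum likelihood.

    ``S`` must cover ``spec.observed`` (a DataFrame is reindexed to that
    order).  The fit is run on the correlation-rescaled covariance for
    numerical balance and mapped back to the input metric afterwards (the
    model family is closed under diagonal rescaling, so this is exact).
    Raises :class:`SemConvergenceError` if no start reaches the gradient
    tolerance.
    """
    obs = spec.observed
    if isinstance(S, pd.DataFrame):
        S = S.loc[obs, obs].to_numpy(float)
    S = np.asarray(S, float)
    p = len(obs)
    if S.shape != (p, p):
        raise ValueError("covariance matrix does not match the observed variables")
    if n <= p:
        raise ValueError("sample size must exceed the number of observed variables")
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin <= 0:
        raise ValueError(f"sample covariance is not positive-definite (min eig {eigmin:.3g})")

    d = np.sqrt(np.diag(S))
    Sc = S / np.outer(d, d)
    ram = _Ram(spec)
    sign, logdet_Sc = np.linalg.slogdet(Sc)
    fun = lambda th: ram.objective_and_grad(th, Sc, logdet_Sc)

    rng = np.random.default_rng(seed)
    starts = []
    base = np.concatenate([np.full(ram.n_paths, 0.5), np.full(ram.m, 0.5)])
    starts.append(base)
    indep = np.concatenate([np.zeros(ram.n_paths),
                            np.concatenate([np.ones(len(spec.latents)), np.diag(Sc)])])
    starts.append(indep)
    for _ in range(max(0, n_starts - 2)):
        starts.append(np.concatenate([
            rng.normal(0.5, 0.5, ram.n_paths),
            rng.uniform(0.2, 1.2, ram.m),
        ]))

    best = None
    for x0 in starts:
        res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 3000, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    # Newton polish: L-BFGS stalls on the flat ridges of this model family
    x, fval = best.x, float(best.fun)
    grad_norm = float(np.max(np.abs(fun(x)[1])))
    grad_fn = lambda th: fun(th)[1]
    for _ in range(4):
        if grad_norm < grad_tol:
            break
        res2 = optimize.minimize(fun, x, jac=True,
                                 hess=lambda th: _numeric_jacobian(grad_fn, th),
                                 method="trust-exact",
                                 options={"maxiter": 300, "gtol": 1e-9})
        if res2.fun <= fval + 1e-12:
            x, fval = res2.x, float(res2.fun)
            grad_norm = float(np.max(np.abs(fun(x)[1])))
        else:
            break
    converged = grad_norm < grad_tol and fval < 1e9
    if not converged:
        raise SemConvergenceError(fval, grad_norm)
    res = optimize.OptimizeResult(x=x, fun=fval)

    # map back from correlation scale to the input metric
    scale = _marker_scales(spec, dict(zip(obs, d)))
    theta_c = res.x.copy()
    theta = theta_c.copy()
    for k, pth in enumerate(spec.free_paths):
        theta[k] = theta_c[k] * scale[pth.dst] / scale[pth.src]
    for i, v in enumerate(ram.vars):
        theta[ram.n_paths + i] = theta_c[ram.n_paths + i] * scale[v] ** 2

    F_min = float(res.fun)
    dfm = model_df(spec)
    chi2 = (n - 1) * F_min
    pval = float(stats.chi2.sf(chi2, dfm)) if dfm > 0 else float("nan")
    Sigma_hat = ram.sigma(theta)

    names = ram.param_names
    se = np.full(ram.n_theta, np.nan)
    if compute_se:
        H = _numeric_hessian(lambda th: fun(th)[0], theta_c)
        try:
            acov_c = 2.0 / (n - 1) * np.linalg.inv(H)
            se_c = np.sqrt(np.clip(np.diag(acov_c), 0, None))
            se = se_c.copy()
            for k, pth in enumerate(spec.free_paths):
                se[k] = se_c[k] * scale[pth.dst] / scale[pth.src]
            for i, v in enumerate(ram.vars):
                se[ram.n_paths + i] = se_c[ram.n_paths + i] * scale[v] ** 2
        except np.linalg.LinAlgError:
            logger.warning("information matrix singular; standard errors unavailable")

    psi = theta[ram.n_paths:]
    heywood = [v for v, val in zip(ram.vars, psi) if val < 0]
    if heywood:
        logger.warning("Heywood case: negative variance estimates for %s", heywood)

    theta_s = pd.Series(theta, index=names, name="estimate")
    se_s = pd.Series(se, index=names, name="se")
    with np.errstate(divide="ignore", invalid="ignore"):
        z_s = pd.Series(theta / se, index=names, name="z")
    return SemFit(
        spec=spec, theta=theta_s, se=se_s, z=z_s,
        Sigma_hat=pd.DataFrame(Sigma_hat, index=obs, columns=obs),
        F_min=F_min, chi2=float(chi2), df=dfm, p=pval, n=n,
        converged=converged, grad_norm=grad_norm, n_starts=len(starts),
        heywood=heywood,
    )


def _numeric_jacobian(g, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Symmetrized central-difference Jacobian of a gradient function."""
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        H[:, i] = (g(xp) - g(xm)) / (2 * h)
    return (H + H.T) / 2


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xi = x.copy(); xi[i] += h; xi[j] += h; fpp = f(xi)
            xi = x.copy(); xi[i] += h; xi[j] -= h; fpm = f(xi)
            xi = x.copy(); xi[i] -= h; xi[j] += h; fmp = f(xi)
            xi = x.copy(); xi[i] -= h; xi[j] -= h; fmm = f(xi)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit_indices(S: pd.DataFrame | np.ndarray, fit: SemFit) -> dict[str, float]:
    """GFI and SRMR comparing the sample and model-implied covariances."""
    obs = fit.spec.observed
    if isinstance(S, pd.DataFrame):
        S = S.loc[obs, obs].to_numpy(float)
    S = np.asarray(S, float)
    Sig = fit.Sigma_hat.to_numpy()
    Sinv = np.linalg.inv(Sig)
    A = Sinv @ S
    I = np.eye(len(obs))
    gfi = 1.0 - np.trace((A - I) @ (A - I)) / np.trace(A @ A)
    d = np.sqrt(np.diag(S))
    resid = (S - Sig) / np.outer(d, d)
    iu = np.triu_indices(len(obs))
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return {"GFI": float(gfi), "SRMR": srmr}


@dataclass
class StdSolution:
    """Standardized (Std.all) loadings, structural paths and residuals."""

    paths: pd.DataFrame        # src, dst, estimate, std_all
    residuals: pd.DataFrame    # variable, variance, std_resid
    heywood: list[str]


def standardize_solution(fit: SemFit) -> StdSolution:
    """Rescale the solution so every variable (latent and observed) has unit
    model-implied variance; marker constraints dissolve in this metric.

    Negative model-implied variances (Heywood symptoms) are handled by
    using |variance| for the scale and flagging the variable.
    """
    return standardize_theta(fit.spec, fit.theta.to_numpy())


def standardize_theta(spec: SemSpec, theta: np.ndarray) -> StdSolution:
    ram = _Ram(spec)
    V = ram.full_cov(np.asarray(theta, float))
    dv = np.diag(V)
    heywood = [v for v, val in zip(ram.vars, dv) if val < 0]
    sd = np.sqrt(np.abs(dv))
    A, psi = ram.matrices(np.asarray(theta, float))
    rows = []
    for p in spec.paths:
        i, j = ram.idx[p.dst], ram.idx[p.src]
        est = A[i, j]
        rows.append(dict(src=p.src, dst=p.dst, estimate=est,
                         std_all=est * sd[j] / sd[i] if sd[i] > 0 else np.nan))
    res_rows = []
    for v in ram.vars:
        i = ram.idx[v]
        res_rows.append(dict(variable=v, variance=psi[i],
                             std_resid=psi[i] / dv[i] if dv[i] != 0 else np.nan))
    hw2 = [r["variable"] for r in res_rows if r["variance"] < 0]
    return StdSolution(paths=pd.DataFrame(rows), residuals=pd.DataFrame(res_rows),
                       heywood=sorted(set(heywood) | set(hw2)))


def implied_sigma(spec: SemSpec, theta: np.ndarray | pd.Series) -> pd.DataFrame:
    """Model-implied covariance of the observed variables at ``theta``."""
    if isinstance(theta, pd.Series):
        theta = theta.to_numpy(float)
    ram = _Ram(spec)
    return pd.DataFrame(ram.sigma(np.asarray(theta, float)),
                        index=spec.observed, columns=spec.observed)


def simulate_sem_data(spec: SemSpec, theta: np.ndarray | pd.Series, n: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw n multivariate-normal observations from Sigma(theta)."""
    Sig = implied_sigma(spec, theta).to_numpy()
    X = rng.multivariate_normal(np.zeros(len(spec.observed)), Sig, size=n,
                                method="cholesky")
    return pd.DataFrame(X, columns=spec.observed)
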