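"""Trait associations: correlations, forward-AIC regression, collinearity
diagnostics and repeated k-fold cross-validation.

All modelling is done on z-standardized adjusted means (sample sd, n-1
denominator), so regression coefficients are standardized betas and the
intercept of the final model is zero up to floating-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fieldbook import logger


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    codes: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample sizes


def _corr_code(p: float) -> str:
    if np.isnan(p):
        return "NA"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def pearson_matrix(X: pd.DataFrame) -> CorrelationMatrix:
    """Pearson r on pairwise-complete observations with two-sided p-values
    from t = r sqrt((n-2)/(1-r^2)), df = n-2, and the significance codes
    *** (p<=0.001), ** (p<=0.01), * (p<=0.05), NS."""
    traits = list(X.columns)
    m = len(traits)
    r = np.eye(m)
    p = np.zeros((m, m))
    n = np.zeros((m, m), int)
    for i in range(m):
        xi = X.iloc[:, i]
        n[i, i] = xi.notna().sum()
        if xi.dropna().nunique() <= 1:
            logger.warning("trait %s has zero variance; correlations set NA", traits[i])
            r[i, :] = r[:, i] = np.nan
            r[i, i] = 1.0
    for i in range(m):
        for j in range(i + 1, m):
            pair = X.iloc[:, [i, j]].dropna()
            nn = len(pair)
            n[i, j] = n[j, i] = nn
            if nn < 3 or np.isnan(r[i, i]) or pair.iloc[:, 0].nunique() <= 1 \
                    or pair.iloc[:, 1].nunique() <= 1:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                continue
            rij = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
            rij = min(1.0, max(-1.0, rij))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((nn - 2) / (1 - rij ** 2))
                pij = 2 * float(stats.t.sf(abs(t), nn - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    codes = pdf.map(_corr_code)
    np.fill_diagonal(codes.values, "")
    return CorrelationMatrix(traits=traits, r=rdf, p=pdf, codes=codes,
                             n=pd.DataFrame(n, index=traits, columns=traits))


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """z-scores by column using the n-1 sample standard deviation."""
    return (X - X.mean()) / X.std(ddof=1)


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with intercept; returns beta, rss, fitted."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta
    rss = float(((y - fitted) ** 2).sum())
    return beta, rss, fitted


def _gaussian_aic(n: int, rss: float, n_params: int) -> float:
    # n_params counts regression coefficients incl. intercept; +1 for sigma
    return n * np.log(max(rss, 1e-300) / n) + 2 * (n_params + 1)


@dataclass
class RegressionFit:
    response: str
    steps: pd.DataFrame      # entered, AIC, RSS, delta_SS, RSE, R2, adjR2, p_added, tie
    coefficients: pd.DataFrame  # term, beta, se, t, p, vif
    adjR2: float
    R2: float
    RSE: float
    F: float
    F_p: float
    cv: dict = field(default_factory=dict)


def forward_aic(y: pd.Series, X: pd.DataFrame) -> RegressionFit:
    """Forward stepwise selection minimizing Gaussian AIC.

    Starts from the intercept-only model; at each step enters the candidate
    giving the lowest AIC, accepting also exact AIC ties (flagged), and
    stops when no candidate lowers (or ties) the current AIC.  Perfectly
    collinear candidates are skipped with a warning.  Returns the step
    ledger and the final standardized-coefficient table with VIFs.
    """
    data = pd.concat([y, X], axis=1).dropna()
    yy = data.iloc[:, 0].to_numpy(float)
    n = len(yy)
    if n <= X.shape[1] + 2:
        raise ValueError("too few observations for the candidate predictor set")
    candidates = list(X.columns)
    entered: list[str] = []
    tss = float(((yy - yy.mean()) ** 2).sum())
    rss_cur = tss
    aic_cur = _gaussian_aic(n, rss_cur, 1)
    rows = []
    while True:
        best = None
        for cand in candidates:
            Xtry = data[entered + [cand]].to_numpy(float)
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xtry])) < len(entered) + 2:
                logger.warning("candidate %s perfectly collinear with entered set; skipped", cand)
                continue
            _, rss, _ = _ols(yy, Xtry)
            aic = _gaussian_aic(n, rss, len(entered) + 2)
            if best is None or aic < best[1] - 1e-12:
                best = (cand, aic, rss)
        if best is None:
            break
        cand, aic, rss = best
        if aic > aic_cur + 1e-9:
            break
        tie = abs(aic - aic_cur) <= 1e-9
        # t-test of the newly added term in the enlarged model
        p_added = _term_pvalues(yy, data[entered + [cand]].to_numpy(float))[-1]
        k = len(entered) + 1
        r2 = 1 - rss / tss
        adj = 1 - (1 - r2) * (n - 1) / (n - k - 1)
        rows.append(dict(entered=cand, AIC=aic, RSS=rss, delta_SS=rss_cur - rss,
                         RSE=np.sqrt(rss / (n - k - 1)), R2=r2, adjR2=adj,
                         p_added=p_added, tie=tie))
        if tie:
            logger.info("predictor %s entered on an exact AIC tie", cand)
        entered.append(cand)
        candidates.remove(cand)
        aic_cur, rss_cur = aic, rss
    if not entered:
        raise ValueError("no predictor improved on the intercept-only model")

    steps = pd.DataFrame(rows)
    Xf = data[entered].to_numpy(float)
    beta, rss, _ = _ols(yy, Xf)
    k = len(entered)
    r2 = 1 - rss / tss
    adj = 1 - (1 - r2) * (n - 1) / (n - k - 1)
    rse = float(np.sqrt(rss / (n - k - 1)))
    if rss > 0:
        F = (tss - rss) / k / (rss / (n - k - 1))
        F_p = float(stats.f.sf(F, k, n - k - 1))
    else:  # exact fit
        F, F_p = np.inf, 0.0
    pvals, ses, tvals = _term_stats(yy, Xf)
    vifs = vif(data[entered]) if k >= 2 else pd.Series([np.nan], index=entered)
    coef = pd.DataFrame({
        "term": entered,
        "beta": beta[1:],
        "se": ses,
        "t": tvals,
        "p": pvals,
        "vif": vifs.reindex(entered).to_numpy(),
    })
    return RegressionFit(response=str(y.name), steps=steps, coefficients=coef,
                         adjR2=adj, R2=r2, RSE=rse, F=float(F), F_p=F_p)


def _term_stats(y: np.ndarray, X: np.ndarray):
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    beta, rss, _ = _ols(y, X)
    dfres = n - Xd.shape[1]
    sigma2 = rss / dfres
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1:] / np.where(se > 0, se, 1.0), np.inf)
    p = 2 * stats.t.sf(np.abs(t), dfres)
    return p, se, t


def _term_pvalues(y: np.ndarray, X: np.ndarray):
    return _term_stats(y, X)[0]


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R2 of x_j on the rest)."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in X.columns:
        others = [c for c in X.columns if c != col]
        yj = X[col].to_numpy(float)
        _, rss, _ = _ols(yj, X[others].to_numpy(float))
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1 - rss / tss if tss > 0 else 1.0
        if r2 >= 1 - 1e-12:
            logger.warning("predictor %s perfectly explained by the others; VIF infinite", col)
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def cross_validate(y: pd.Series, X: pd.DataFrame, k: int = 10, repeats: int = 10,
                   seed: int = 0) -> dict:
    """Repeated k-fold CV of the OLS fit of y on X.

    Folds are random partitions (fresh permutation each repeat) from a
    numpy Generator seeded with ``seed``, so results are reproducible.
    Reports mean +/- sd of RMSE, MAE and out-of-fold R2 across repeats.
    """
    data = pd.concat([y, X], axis=1).dropna()
    yy = data.iloc[:, 0].to_numpy(float)
    XX = data.iloc[:, 1:].to_numpy(float)
    n = len(yy)
    if k > n:
        raise ValueError("more folds than observations")
    if n < 2 * k:
        raise ValueError("need at least 2k observations for k-fold CV")
    rng = np.random.default_rng(seed)
    rmses, maes, r2s = [], [], []
    for _ in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        pred = np.empty(n)
        for fold in folds:
            train = np.setdiff1d(perm, fold, assume_unique=False)
            Xtr = np.column_stack([np.ones(len(train)), XX[train]])
            beta, *_ = np.linalg.lstsq(Xtr, yy[train], rcond=None)
            pred[fold] = np.column_stack([np.ones(len(fold)), XX[fold]]) @ beta
        err = yy - pred
        rmses.append(float(np.sqrt(np.mean(err ** 2))))
        maes.append(float(np.mean(np.abs(err))))
        r2s.append(float(1 - np.sum(err ** 2) / np.sum((yy - yy.mean()) ** 2)))
    return {
        "k": k, "repeats": repeats, "seed": seed, "n": n,
        "rmse_mean": float(np.mean(rmses)), "rmse_sd": float(np.std(rmses, ddof=1)) if repeats > 1 else 0.0,
        "mae_mean": float(np.mean(maes)), "mae_sd": float(np.std(maes, ddof=1)) if repeats > 1 else 0.0,
        "r2_mean": float(np.mean(r2s)), "r2_sd": float(np.std(r2s, ddof=1)) if repeats > 1 else 0.0,
    }
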