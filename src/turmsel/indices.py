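"""Multi-trait selection indices: MGIDI, MTSI, FAI and Smith-Hazel.

The ideotype-based indices work on traits rescaled to 0-100 so that 100
is always the most desirable value; an exploratory factor analysis
(principal-component extraction on the correlation matrix, eigenvalue > 1
retention, varimax rotation, regression-method scores) collapses the
rescaled traits into a few orthogonal factors, and each genotype is ranked
by its Euclidean distance in factor-score space from the ideotype (MGIDI,
MTSI) or by its relative proximity to the ideotype versus the
anti-ideotype (FAI).  The Smith-Hazel index is the classical linear
phenotypic index b'x with b = P^-1 G w.  Selection gains discount the
selection differential of the chosen set by heritability, and the
coincidence analysis counts genotypes jointly selected by pairs of
methods.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fieldbook import TraitSpec, logger


def n_selected(si: float, n: int) -> int:
    """Selected-set size at intensity ``si``: round half-up of si * n."""
    return int(math.floor(si * n + 0.5))


def rescale_traits(means: pd.DataFrame, traits: list[TraitSpec]) -> pd.DataFrame:
    """Min-max rescale each trait to 0-100 with 100 most desirable.

    Traits with direction ``decrease`` are reversed.  A constant trait
    cannot be rescaled and raises ``ValueError``.
    """
    spec_by_name = {t.name: t for t in traits}
    out = {}
    for col in means.columns:
        x = means[col].astype(float)
        lo, hi = x.min(), x.max()
        if not hi > lo:
            raise ValueError(f"trait {col} is constant; cannot rescale")
        scaled = 100.0 * (x - lo) / (hi - lo)
        t = spec_by_name.get(col)
        if t is not None and t.direction == "decrease":
            scaled = 100.0 - scaled
        out[col] = scaled
    return pd.DataFrame(out, index=means.index)


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation by Kaiser's pairwise planar rotations.

    Each factor pair is rotated by its closed-form optimal angle; sweeps
    repeat until no pair moves.  More robust than the gradient/SVD scheme
    at the symmetric configurations that arise with block-structured data.
    """
    p, k = L.shape
    L = L.copy()
    if k == 1:
        return L
    for _ in range(max_iter):
        moved = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                u = L[:, i] ** 2 - L[:, j] ** 2
                v = 2.0 * L[:, i] * L[:, j]
                A, B = u.sum(), v.sum()
                C = (u ** 2 - v ** 2).sum()
                D = (2.0 * u * v).sum()
                num = D - 2.0 * A * B / p
                den = C - (A ** 2 - B ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                Li = L[:, i] * c + L[:, j] * s
                Lj = -L[:, i] * s + L[:, j] * c
                L[:, i], L[:, j] = Li, Lj
                moved = max(moved, abs(phi))
        if moved < tol:
            break
    return L


@dataclass
class FactorModel:
    """Varimax-rotated factor solution on rescaled traits, with the score
    weights needed to project new rows (the ideotype) consistently."""

    loadings: pd.DataFrame          # trait x factor (rotated)
    eigenvalues: np.ndarray
    retained_k: int
    communalities: pd.Series
    uniquenesses: pd.Series
    scores: pd.DataFrame            # genotype x factor
    variance_explained_pct: np.ndarray
    col_means: pd.Series
    col_sds: pd.Series
    score_weights: np.ndarray       # R^-1 L, trait x factor

    def project(self, row: pd.Series) -> np.ndarray:
        """Factor scores of a new trait profile via the fitted weights."""
        z = ((row[self.loadings.index] - self.col_means) / self.col_sds).to_numpy(float)
        return z @ self.score_weights


def factor_analysis(X: pd.DataFrame, retain_rule: str = "eigen_gt_1") -> FactorModel:
    """Principal-component factor extraction with varimax rotation.

    Factors with pre-rotation eigenvalue > 1 are retained (if all
    eigenvalues tie at exactly 1, one factor is kept with a warning);
    scores use the regression method Z R^-1 L.
    """
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more genotypes than traits for factor analysis")
    mu, sd = X.mean(), X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant traits: {list(sd.index[sd == 0])}")
    Z = (X - mu) / sd
    R = np.corrcoef(Z.to_numpy(float), rowvar=False)
    eig, vec = np.linalg.eigh(R)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    k = int((eig > 1 + 1e-10).sum())
    if k < 1:
        if np.allclose(eig, 1.0):
            logger.warning("all eigenvalues tie at 1; retaining a single factor")
            k = 1
        else:
            raise ValueError("no factor with eigenvalue > 1")
    L = vec[:, :k] * np.sqrt(eig[:k])
    L = _varimax(L)
    # deterministic sign: dominant loading of each factor positive
    for f in range(k):
        if L[np.argmax(np.abs(L[:, f])), f] < 0:
            L[:, f] *= -1
    # order factors by explained variance after rotation
    ss = (L ** 2).sum(axis=0)
    L = L[:, np.argsort(ss)[::-1]]
    ss = (L ** 2).sum(axis=0)

    names = [f"FA{i + 1}" for i in range(k)]
    Rinv = np.linalg.pinv(R)
    W = Rinv @ L
    scores = Z.to_numpy(float) @ W
    comm = pd.Series((L ** 2).sum(axis=1), index=X.columns, name="communality")
    return FactorModel(
        loadings=pd.DataFrame(L, index=X.columns, columns=names),
        eigenvalues=eig,
        retained_k=k,
        communalities=comm,
        uniquenesses=1.0 - comm,
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        variance_explained_pct=100.0 * ss / len(X.columns),
        col_means=mu,
        col_sds=sd,
        score_weights=W,
    )


@dataclass
class IndexResult:
    method: str
    scores: pd.Series               # genotype -> index value
    ranking: list[str]              # best first
    selected: list[str]
    gains: pd.DataFrame | None = None
    factor_contributions: pd.DataFrame | None = None
    b_vector: pd.Series | None = None


def _rank_and_select(scores: pd.Series, ascending: bool, si: float,
                     method: str) -> tuple[list[str], list[str]]:
    # ties broken by genotype label, deterministically
    df = scores.rename("score").reset_index()
    df.columns = ["genotype", "score"]
    df = df.sort_values(["score", "genotype"], ascending=[ascending, True])
    ranking = df["genotype"].tolist()
    sel = ranking[: n_selected(si, len(ranking))]
    logger.info("%s: selected %d of %d genotypes", method, len(sel), len(ranking))
    return ranking, sel


def mgidi(fm: FactorModel, ideotype_scores: np.ndarray, si: float = 0.20) -> IndexResult:
    """Multi-trait genotype-ideotype distance index: Euclidean distance in
    factor-score space from the (all-100) ideotype; smallest is best."""
    diff = fm.scores.to_numpy(float) - np.asarray(ideotype_scores, float)
    dist = np.sqrt((diff ** 2).sum(axis=1))
    scores = pd.Series(dist, index=fm.scores.index, name="MGIDI")
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (diff ** 2) / np.where(dist[:, None] == 0, np.nan, dist[:, None] ** 2)
    ranking, sel = _rank_and_select(scores, ascending=True, si=si, method="MGIDI")
    return IndexResult(
        method="MGIDI", scores=scores, ranking=ranking, selected=sel,
        factor_contributions=pd.DataFrame(contrib, index=fm.scores.index,
                                          columns=fm.scores.columns),
    )


def fai(fm: FactorModel, si: float = 0.20) -> IndexResult:
    """Factor-analysis/ideotype index: probability-style proximity to the
    all-100 ideotype versus the all-0 anti-ideotype; largest is best."""
    traits = fm.loadings.index
    ideo = fm.project(pd.Series(100.0, index=traits))
    anti = fm.project(pd.Series(0.0, index=traits))
    F = fm.scores.to_numpy(float)
    d_id = np.sqrt(((F - ideo) ** 2).sum(axis=1))
    d_an = np.sqrt(((F - anti) ** 2).sum(axis=1))
    p = np.empty(len(F))
    for i, (di, da) in enumerate(zip(d_id, d_an)):
        if di == 0:
            p[i] = 1.0
        elif da == 0:
            p[i] = 0.0
        else:
            p[i] = (1 / di) / (1 / di + 1 / da)
    scores = pd.Series(p, index=fm.scores.index, name="FAI")
    ranking, sel = _rank_and_select(scores, ascending=False, si=si, method="FAI")
    return IndexResult(method="FAI", scores=scores, ranking=ranking, selected=sel)


def mtsi(per_year_means: dict[str, pd.DataFrame], traits: list[TraitSpec],
         si: float = 0.20, theta: float = 0.5) -> IndexResult:
    """Multi-trait stability index for a two-year trial.

    Blends rescaled mean performance with a rescaled stability score
    (negative absolute between-year difference, so 100 = perfectly
    stable): Y* = theta * performance + (1 - theta) * stability, then an
    MGIDI-style distance to the all-100 ideotype on Y*.
    """
    years = sorted(per_year_means)
    if len(years) < 2:
        raise ValueError("MTSI needs at least two years; use MGIDI for one environment")
    common = per_year_means[years[0]].index
    for yr in years[1:]:
        common = common.intersection(per_year_means[yr].index)
    mats = [per_year_means[yr].loc[common] for yr in years]
    mean_perf = sum(mats) / len(mats)
    perf = rescale_traits(mean_perf, traits)
    instab = sum((m - mean_perf).abs() for m in mats)
    stab = pd.DataFrame(index=common, columns=mean_perf.columns, dtype=float)
    for col in mean_perf.columns:
        neg = -instab[col].astype(float)
        lo, hi = neg.min(), neg.max()
        if hi > lo:
            stab[col] = 100.0 * (neg - lo) / (hi - lo)
        else:
            stab[col] = 100.0  # all genotypes equally stable
    Y = theta * perf + (1 - theta) * stab
    fm = factor_analysis(Y)
    ideo = fm.project(pd.Series(100.0, index=Y.columns))
    res = mgidi(fm, ideo, si=si)
    res.scores.name = "MTSI"
    return IndexResult(method="MTSI", scores=res.scores, ranking=res.ranking,
                       selected=res.selected, factor_contributions=res.factor_contributions)


def smith_hazel(P: pd.DataFrame, G: pd.DataFrame, w: pd.Series,
                means: pd.DataFrame, si: float = 0.20,
                p_for_k: float | None = None) -> IndexResult:
    """Smith-Hazel linear index: b = P^-1 G w, index I = b'x on
    standardized means; largest is best.

    A singular phenotypic matrix is ridge-regularized (lambda =
    1e-8 * trace) with a warning.  The expected aggregate response vector
    R = k G b / sqrt(b'Pb) is attached as ``gains`` when ``p_for_k`` is
    given.
    """
    traits = list(P.columns)
    Pm = P.loc[traits, traits].to_numpy(float)
    Gm = G.loc[traits, traits].to_numpy(float)
    wv = w.reindex(traits).to_numpy(float)
    try:
        Pinv = np.linalg.inv(Pm)
        if np.linalg.cond(Pm) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        lam = 1e-8 * np.trace(Pm)
        logger.warning("phenotypic covariance singular; ridge lambda=%.3g applied", lam)
        Pinv = np.linalg.inv(Pm + lam * np.eye(len(traits)))
    b = Pinv @ Gm @ wv
    Z = (means[traits] - means[traits].mean()) / means[traits].std(ddof=1)
    idx = pd.Series(Z.to_numpy(float) @ b, index=means.index, name="SH")
    ranking, sel = _rank_and_select(idx, ascending=False, si=si, method="SH")
    gains = None
    if p_for_k is not None:
        from .genparams import selection_intensity
        k = selection_intensity(p_for_k)
        denom = float(np.sqrt(b @ Pm @ b))
        if denom > 0:
            resp = k * (Gm @ b) / denom
            gains = pd.DataFrame({"trait": traits, "expected_response": resp})
    return IndexResult(method="SH", scores=idx, ranking=ranking, selected=sel,
                       gains=gains, b_vector=pd.Series(b, index=traits, name="b"))


def selection_gains(means: pd.DataFrame, selected: list[str],
                    h2: dict[str, float]) -> pd.DataFrame:
    """Per-trait selection differential and percentage gain.

    D_t = mean(selected) - mean(all); SG%_t = 100 * H2_t * D_t / mean(all),
    with H2 as a proportion in [0, 1].
    """
    if not selected:
        raise ValueError("empty selected set")
    rows = []
    sel = means.loc[means.index.intersection(selected)]
    for trait in means.columns:
        mu_all = float(means[trait].mean())
        diff = float(sel[trait].mean()) - mu_all
        h = h2.get(trait, np.nan)
        if mu_all == 0:
            logger.warning("trait %s: zero population mean; SG%% undefined", trait)
            sg = np.nan
        else:
            sg = 100.0 * h * diff / mu_all
        rows.append(dict(trait=trait, mean_all=mu_all,
                         mean_selected=float(sel[trait].mean()),
                         differential=diff, H2=h, SG_pct=sg))
    return pd.DataFrame(rows)


@dataclass
class CoincidenceResult:
    pairwise: pd.DataFrame          # method_a, method_b, n_common, pct
    all_methods_common: list[str]
    venn_partition_counts: dict[str, int] = field(default_factory=dict)


def coincidence(selected_sets: dict[str, set[str] | list[str]]) -> CoincidenceResult:
    """Pairwise overlap of selected sets, the cross-method intersection and
    Venn partition counts.  Percentages use the selected-set size (the
    pair's smaller size, with a warning, if sizes differ)."""
    methods = sorted(selected_sets)
    if len(methods) < 2:
        raise ValueError("need at least two selection methods")
    sets = {m: set(selected_sets[m]) for m in methods}
    sizes = {m: len(s) for m, s in sets.items()}
    if len(set(sizes.values())) > 1:
        logger.warning("unequal selected-set sizes %s; percentages use the pair minimum", sizes)
    rows = []
    for a, b in itertools.combinations(methods, 2):
        common = sets[a] & sets[b]
        denom = min(sizes[a], sizes[b])
        rows.append(dict(method_a=a, method_b=b, n_common=len(common),
                         pct=100.0 * len(common) / denom if denom else np.nan))
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    venn: dict[str, int] = {}
    for g in union:
        key = "&".join(m for m in methods if g in sets[m])
        venn[key] = venn.get(key, 0) + 1
    return CoincidenceResult(pairwise=pd.DataFrame(rows),
                             all_methods_common=sorted(inter),
                             venn_partition_counts=venn)
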