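"""Federer adjustment and ANOVA for augmented randomized complete block designs.

In an ARCBD the replicated checks estimate block effects and experimental
error, and each unreplicated test entry's mean is corrected by the effect
of the block it happened to land in:

    b_j = (mean of checks in block j) - (grand mean of checks)
    V_i = u_i - b_j                      (tests)
    V_c = mean over the check's plots    (checks; block effects cancel)

The ANOVA partitions the genotype stratum (ignoring blocks) into checks,
tests and tests-vs-checks, with blocks eliminating genotypes and a
residual estimated from check replication.  Precision statistics (CD,
SE(m), CV%) follow the standard augmented-design formulas; all four
Federer standard errors of a difference are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fieldbook import FieldBook, logger


class BlockEffectError(ValueError):
    """A block lacks check data needed to estimate its effect."""


def _year_trait_frame(fb: FieldBook, year: str, trait: str) -> pd.DataFrame:
    df = fb.to_frame()
    if trait not in df.columns:
        raise KeyError(f"trait {trait} not in field book")
    sub = df.loc[df["year"] == str(year), ["block", "genotype", "role", trait]].copy()
    if sub.empty:
        raise KeyError(f"year {year} not in field book")
    sub = sub.rename(columns={trait: "value"})
    return sub


def estimate_block_effects(fb: FieldBook, year: str, trait: str) -> dict[str, float]:
    """Check-based block effects b_j, summing to zero over blocks."""
    sub = _year_trait_frame(fb, year, trait)
    checks = sub[sub["role"] == "check"].dropna(subset=["value"])
    check_set = set(sub.loc[sub["role"] == "check", "genotype"])
    effects: dict[str, float] = {}
    grand = checks["value"].mean()
    for block, bdf in checks.groupby("block", sort=True):
        missing = check_set - set(bdf["genotype"])
        if missing:
            raise BlockEffectError(
                f"block {block} (year {year}, trait {trait}) is missing check "
                f"values for: {sorted(missing)}")
        effects[block] = float(bdf["value"].mean() - grand)
    absent = set(sub["block"]) - set(effects)
    if absent:
        raise BlockEffectError(
            f"blocks without any check data for trait {trait}, year {year}: {sorted(absent)}")
    return effects


def adjust_means(fb: FieldBook, year: str, trait: str) -> pd.DataFrame:
    """Block-adjusted genotype means for one year and trait.

    Returns a frame with columns genotype, role, raw_mean, block_effect,
    adjusted_mean; ``attrs`` carry the year and trait.  Tests are adjusted
    by their block's effect; checks get the plain mean of their replicate
    plots (a check's block effects cancel by construction).
    """
    sub = _year_trait_frame(fb, year, trait)
    effects = estimate_block_effects(fb, year, trait)
    rows = []
    for geno, gdf in sub.dropna(subset=["value"]).groupby("genotype", sort=True):
        role = gdf["role"].iloc[0]
        u = float(gdf["value"].mean())
        if role == "test":
            b = effects[gdf["block"].iloc[0]]
            rows.append((geno, role, u, b, u - b))
        else:
            rows.append((geno, role, u, 0.0, u))
    out = pd.DataFrame(rows, columns=["genotype", "role", "raw_mean",
                                      "block_effect", "adjusted_mean"])
    out.attrs.update({"year": str(year), "trait": trait})
    return out


def check_residuals(fb: FieldBook, year: str, trait: str) -> np.ndarray:
    """Residuals of the check plots after removing check and block effects.

    These carry the experimental-error information of the ARCBD and are the
    inputs to the across-year homogeneity (Bartlett) test.
    """
    sub = _year_trait_frame(fb, year, trait)
    checks = sub[sub["role"] == "check"].dropna(subset=["value"])
    effects = estimate_block_effects(fb, year, trait)
    geno_mean = checks.groupby("genotype")["value"].transform("mean")
    b = checks["block"].map(effects)
    return (checks["value"] - geno_mean - b).to_numpy(float)


@dataclass
class AnovaTable:
    """Augmented-design ANOVA with the genotype stratum sub-partitioned."""

    table: pd.DataFrame  # columns: source, df, SS, MS, F, p, sig
    grand_mean: float
    n_blocks: int
    n_checks: int
    n_tests: int

    def _row(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    @property
    def ms_residual(self) -> float:
        return float(self._row("Residuals")["MS"])

    @property
    def df_residual(self) -> int:
        return int(self._row("Residuals")["df"])

    @property
    def ms_tests(self) -> float:
        return float(self._row("Genotypes: tests")["MS"])


def _sig_code(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def arcbd_anova(fb: FieldBook, year: str, trait: str) -> AnovaTable:
    """Sequential ANOVA: genotypes (ignoring blocks) first, then blocks
    (eliminating genotypes), residual from check replication.

    The genotype sum of squares is partitioned into between-check,
    between-test, and tests-vs-checks components, which sum exactly to the
    genotype SS.  F-tests use the residual mean square.
    """
    sub = _year_trait_frame(fb, year, trait).dropna(subset=["value"])
    y = sub["value"].to_numpy(float)
    n = y.size
    genos = sub["genotype"].to_numpy()
    blocks = sub["block"].to_numpy()
    roles = sub["role"].to_numpy()
    g_levels = pd.unique(genos)
    b_levels = pd.unique(blocks)
    c = int(pd.unique(genos[roles == "check"]).size)
    n_tests = int(pd.unique(genos[roles == "test"]).size)
    if c < 2 or len(b_levels) < 2:
        raise ValueError("ARCBD ANOVA needs at least two checks and two blocks "
                         "(one check leaves the residual inestimable)")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    # genotype stratum, ignoring blocks
    gm = pd.Series(y).groupby(genos).agg(["mean", "size"])
    ss_geno = float((gm["size"] * (gm["mean"] - grand) ** 2).sum())

    is_check = roles == "check"
    yc, yt = y[is_check], y[~is_check]
    gc = pd.Series(yc).groupby(genos[is_check]).agg(["mean", "size"])
    gt = pd.Series(yt).groupby(genos[~is_check]).agg(["mean", "size"])
    ss_checks = float((gc["size"] * (gc["mean"] - yc.mean()) ** 2).sum())
    ss_tests = float((gt["size"] * (gt["mean"] - yt.mean()) ** 2).sum())
    ss_tvc = float(yc.size * (yc.mean() - grand) ** 2 + yt.size * (yt.mean() - grand) ** 2)

    # full two-way fit (genotype + block, both as factors): residual SS
    Xg = pd.get_dummies(pd.Categorical(genos, categories=g_levels), drop_first=True)
    Xb = pd.get_dummies(pd.Categorical(blocks, categories=b_levels), drop_first=True)
    X = np.column_stack([np.ones(n), Xg.to_numpy(float), Xb.to_numpy(float)])
    _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
    ss_resid = float(((y - fitted) ** 2).sum())
    ss_block = ss_total - ss_geno - ss_resid

    df_geno = len(g_levels) - 1
    df_block = len(b_levels) - 1
    df_resid = n - rank
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    ms_resid = ss_resid / df_resid

    def row(source, df, ss, test=True):
        ms = ss / df if df > 0 else np.nan
        if test and df > 0 and ms_resid > 0:
            F = ms / ms_resid
            p = float(stats.f.sf(F, df, df_resid))
        else:
            F, p = np.nan, np.nan
        return dict(source=source, df=df, SS=ss, MS=ms, F=F, p=p, sig=_sig_code(p))

    table = pd.DataFrame([
        row("Genotypes (ignoring blocks)", df_geno, ss_geno),
        row("Genotypes: checks", c - 1, ss_checks),
        row("Genotypes: tests", n_tests - 1, ss_tests),
        row("Genotypes: tests vs checks", 1, ss_tvc),
        row("Block (eliminating genotypes)", df_block, ss_block),
        row("Residuals", df_resid, ss_resid, test=False),
    ])
    logger.debug("ANOVA %s/%s: MS_tests=%.4g MS_resid=%.4g", year, trait,
                 table.loc[2, "MS"], ms_resid)
    return AnovaTable(table=table, grand_mean=float(grand), n_blocks=len(b_levels),
                      n_checks=c, n_tests=n_tests)


@dataclass
class PrecisionStats:
    """Trial precision: critical difference (test-test, different blocks),
    standard error of a mean, coefficient of variation, and the four
    Federer standard errors of a difference."""

    CD: float
    SEm: float
    CV_pct: float
    sed: dict[str, float]
    t_crit: float


def precision_stats(anova: AnovaTable, alpha: float = 0.05) -> PrecisionStats:
    """CD/SE(m)/CV% from the residual mean square of an ARCBD ANOVA."""
    mse = anova.ms_residual
    edf = anova.df_residual
    if edf <= 0:
        raise ValueError("zero residual degrees of freedom")
    b, c = anova.n_blocks, anova.n_checks
    t_crit = float(stats.t.ppf(1 - alpha / 2, edf))
    sed = {
        "check_check": float(np.sqrt(2 * mse / b)),
        "test_test_same_block": float(np.sqrt(2 * mse)),
        "test_test_diff_block": float(np.sqrt(2 * mse * (1 + 1 / c))),
        "test_check": float(np.sqrt(mse * (1 + 1 / b + 1 / c + 1 / (b * c)))),
    }
    cv = 100.0 * np.sqrt(mse) / anova.grand_mean if anova.grand_mean != 0 else np.nan
    return PrecisionStats(
        CD=t_crit * sed["test_test_diff_block"],
        SEm=float(np.sqrt(mse / b)),
        CV_pct=float(cv),
        sed=sed,
        t_crit=t_crit,
    )
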