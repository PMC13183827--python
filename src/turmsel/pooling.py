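"""Across-year pooling of adjusted means.

Once each year's field book has been reduced to block-adjusted genotype
means, the two years form a balanced genotype x year table with one value
per cell.  Years are treated as fixed, genotypes and genotype-by-year as
random; with one observation per cell the G x Y interaction is confounded
with error, so a single ``sigma2_gy`` component is reported.  Variance
components come from the expected mean squares of the two-way ANOVA
(on this balanced layout the moment estimator coincides in expectation
with REML).

Bartlett's chi-square test checks homogeneity of the years' error
variances before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fieldbook import logger


@dataclass
class BartlettResult:
    statistic: float
    df: int
    p: float


def bartlett_test(samples: Sequence[np.ndarray]) -> BartlettResult:
    """Classical Bartlett homogeneity-of-variances test across k groups."""
    samples = [np.asarray(s, float) for s in samples]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two values")
    if any(np.var(s, ddof=1) == 0 for s in samples):
        raise ValueError("a group has zero variance; Bartlett statistic undefined")
    stat, p = stats.bartlett(*samples)
    return BartlettResult(statistic=float(stat), df=len(samples) - 1, p=float(p))


@dataclass
class PooledVarComp:
    """Pooled genotype means and across-year variance components for one trait."""

    trait: str
    sigma2_g: float
    sigma2_gy: float  # G x year interaction, confounded with error
    n_years: int
    n_genotypes: int
    pooled_means: pd.Series  # genotype -> mean over years
    negative_g_floored: bool
    ms_g: float
    ms_gy: float


def pool_years(per_year_means: Mapping[str, pd.DataFrame], trait: str) -> PooledVarComp:
    """Two-way genotype x year ANOVA on adjusted means (one value per cell).

    ``per_year_means`` maps year label -> adjusted-means frame (as produced
    by :func:`turmsel.arcbd.adjust_means`).  Only genotypes present in every
    year enter.  Components: sigma2_gy = MS_GY; sigma2_g =
    max(0, (MS_G - MS_GY) / n_years), floored at zero with a flag.
    """
    years = sorted(per_year_means)
    if len(years) < 2:
        raise ValueError("pooling needs at least two years")
    cols = {}
    for yr in years:
        tbl = per_year_means[yr]
        cols[yr] = tbl.set_index("genotype")["adjusted_mean"]
    wide = pd.DataFrame(cols).dropna()
    g, y = wide.shape
    if g < 2:
        raise ValueError("fewer than two genotypes common to all years")

    vals = wide.to_numpy(float)
    grand = vals.mean()
    geno_means = vals.mean(axis=1)
    year_means = vals.mean(axis=0)
    ss_g = y * float(((geno_means - grand) ** 2).sum())
    ss_y = g * float(((year_means - grand) ** 2).sum())
    ss_tot = float(((vals - grand) ** 2).sum())
    ss_gy = ss_tot - ss_g - ss_y
    ms_g = ss_g / (g - 1)
    ms_gy = ss_gy / ((g - 1) * (y - 1))
    raw = (ms_g - ms_gy) / y
    floored = raw < 0
    if floored:
        logger.warning("trait %s: negative genotypic variance estimate %.4g floored to 0",
                       trait, raw)
    return PooledVarComp(
        trait=trait,
        sigma2_g=max(0.0, raw),
        sigma2_gy=ms_gy,
        n_years=y,
        n_genotypes=g,
        pooled_means=wide.mean(axis=1).rename(trait),
        negative_g_floored=bool(floored),
        ms_g=ms_g,
        ms_gy=ms_gy,
    )
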