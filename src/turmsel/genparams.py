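"""Variance components and genetic parameters for breeding trials.

From the augmented-design ANOVA the phenotypic variance of the test
population is taken as the mean square of the test-entry stratum and the
error variance as the residual mean square, so that

    sigma2_g = sigma2_p - sigma2_e        (NA when <= 0)
    GCV%     = 100 * sqrt(sigma2_g) / mean
    PCV%     = 100 * sqrt(sigma2_p) / mean
    H2%      = 100 * sigma2_g / sigma2_p   (broad sense)
    GA       = k * sigma_p * H2            (classical truncation-selection form,
                                            = k * sigma2_g / sigma_p)

where k is the standardized selection differential at the chosen selected
proportion (k = 2.063 at 5%).  An alternative convention GA = k * sigma_g
* H2 is selectable via ``ga_formula="as_printed"``.  GCV/PCV are labelled
low (<10%), moderate (10-20%] and high (>20%); H2 low (<30%), moderate
(30-60%] and high (>60%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .fieldbook import TraitSpec, logger


@dataclass
class VarianceComponents:
    trait: str
    mean: float
    sigma2_p: float
    sigma2_e: float
    sigma2_g: float | None  # None (reported NA) when sigma2_p <= sigma2_e


@dataclass
class GeneticParams:
    trait: str
    GCV_pct: float | None
    PCV_pct: float
    H2_pct: float | None
    GA: float | None
    GA_pct_of_mean: float | None
    k: float
    categories: dict[str, str | None]


def variance_components(ms_test: float, ms_resid: float, mean: float,
                        trait: str = "") -> VarianceComponents:
    """sigma2_p from the test-entry mean square, sigma2_e from the residual."""
    if ms_test < 0 or ms_resid < 0:
        raise ValueError("mean squares must be non-negative")
    s2g = ms_test - ms_resid
    if s2g <= 0:
        logger.warning("trait %s: sigma2_p <= sigma2_e; genotypic variance reported NA", trait)
        s2g_out = None
    else:
        s2g_out = s2g
    return VarianceComponents(trait=trait, mean=mean, sigma2_p=ms_test,
                              sigma2_e=ms_resid, sigma2_g=s2g_out)


def selection_intensity(p: float) -> float:
    """Standardized selection differential k = phi(z_p)/p for truncation
    selection of the upper proportion p of a standard normal."""
    if not 0 < p < 1:
        raise ValueError("selected proportion must lie strictly in (0, 1)")
    z = stats.norm.ppf(1 - p)
    return float(stats.norm.pdf(z) / p)


def _cv_category(v: float | None) -> str | None:
    if v is None or math.isnan(v):
        return None
    if v < 10:
        return "low"
    if v <= 20:
        return "moderate"
    return "high"


def _h2_category(v: float | None) -> str | None:
    if v is None or math.isnan(v):
        return None
    if v < 30:
        return "low"
    if v <= 60:
        return "moderate"
    return "high"


def genetic_params(vc: VarianceComponents, p_selected: float = 0.05,
                   ga_formula: str = "classical") -> GeneticParams:
    """GCV/PCV/H2/GA with category labels from variance components.

    When sigma2_g is NA, only PCV is computed; the rest propagate NA.
    """
    if vc.mean <= 0:
        raise ValueError("trait mean must be positive for coefficients of variation")
    if ga_formula not in ("classical", "as_printed"):
        raise ValueError("ga_formula must be 'classical' or 'as_printed'")
    k = selection_intensity(p_selected)
    pcv = 100.0 * math.sqrt(vc.sigma2_p) / vc.mean
    if vc.sigma2_g is None:
        return GeneticParams(trait=vc.trait, GCV_pct=None, PCV_pct=pcv, H2_pct=None,
                             GA=None, GA_pct_of_mean=None, k=k,
                             categories={"GCV": None, "PCV": _cv_category(pcv), "H2": None})
    gcv = 100.0 * math.sqrt(vc.sigma2_g) / vc.mean
    h2 = vc.sigma2_g / vc.sigma2_p  # in [0, 1]
    sigma_p = math.sqrt(vc.sigma2_p)
    sigma_g = math.sqrt(vc.sigma2_g)
    if ga_formula == "classical":
        ga = k * sigma_p * h2  # == k * sigma2_g / sigma_p
    else:
        ga = k * sigma_g * h2
    return GeneticParams(
        trait=vc.trait, GCV_pct=gcv, PCV_pct=pcv, H2_pct=100.0 * h2,
        GA=ga, GA_pct_of_mean=100.0 * ga / vc.mean, k=k,
        categories={"GCV": _cv_category(gcv), "PCV": _cv_category(pcv),
                    "H2": _h2_category(100.0 * h2)},
    )


def count_in_ideotype_window(means: pd.DataFrame, traits: list[TraitSpec]) -> dict[str, int]:
    """Count genotypes whose mean lies inside each trait's closed ideotype window.

    ``means`` is a genotype x trait frame (trait codes as columns).  Traits
    without a configured window are skipped with a warning.
    """
    counts: dict[str, int] = {}
    for t in traits:
        if t.name not in means.columns:
            continue
        if t.ideotype_window is None:
            logger.warning("trait %s has no ideotype window; skipped", t.name)
            continue
        lo, hi = t.ideotype_window
        col = means[t.name].dropna()
        counts[t.name] = int(((col >= lo) & (col <= hi)).sum())
    return counts
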