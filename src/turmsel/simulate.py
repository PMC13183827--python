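"""Synthetic augmented-design half-sib trial generator with known truth.

The generator mirrors the biology the pipeline is meant to analyse.  Each
genotype i carries a standardized latent vegetative vigor VEG_i (family
mean + within-family deviation, emulating half-sib structure under open
pollination) and a latent rhizome sink strength

    SINK_i = beta * VEG_i + zeta_i,        var(SINK) = 1,

so vegetative vigor drives sink capacity.  A trait's genotypic value is

    g_it = mu_t + sqrt(s2g_t) * (lv_t VEG_i + ls_t SINK_i + lu_t U_it),

with standardized loadings lv, ls and a unique genetic deviation filling
the remainder (lu^2 = 1 - lv^2 - ls^2 - 2 beta lv ls), so the total
genotypic variance equals the configured s2g_t and the genetic
correlations follow the latent source-sink network.  Dry recovery loads
negatively on SINK, creating the yield-quality trade-off.  Plot values
add a fixed year offset, genotype-by-year noise, a small block effect and
plot error; checks are replicated in every block, tests planted once per
year in a randomly assigned block.

Default trait means, genotypic variances and heritabilities are set to
magnitudes typical of a two-year turmeric half-sib trial (total yield
mean 0.5 kg/plant with H2 ~ 0.8, dry recovery mean 22.4% with H2 ~ 0.96,
and so on); block variance is kept small relative to plot error, matching
the generally non-significant block effects of a well-run augmented
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fieldbook import FieldBook, PlotRecord, TraitSpec, logger, read_trait_config


@dataclass(frozen=True)
class TraitSim:
    """Generative settings for one trait (loadings standardized)."""

    name: str
    mean: float
    sigma2_g: float      # total genotypic variance
    sigma2_e: float      # plot error variance
    sigma2_gy: float     # genotype-by-year variance
    loading_veg: float
    loading_sink: float

    def unique_share(self, beta: float) -> float:
        lu2 = 1.0 - self.loading_veg ** 2 - self.loading_sink ** 2 \
            - 2.0 * beta * self.loading_veg * self.loading_sink
        if lu2 < 0:
            raise ValueError(f"trait {self.name}: loadings imply negative unique variance")
        return lu2


def _trait(name, mean, s2g, h2, lv, ls, gy_frac=0.10):
    s2e = s2g * (1 - h2) / h2
    return TraitSim(name=name, mean=mean, sigma2_g=s2g, sigma2_e=s2e,
                    sigma2_gy=gy_frac * s2g, loading_veg=lv, loading_sink=ls)


# magnitudes of a typical two-year turmeric half-sib trial
_DEFAULT_TRAITS = [
    _trait("PH", 98.15, 116.70, 0.89, 0.60, 0.00),
    _trait("NT", 3.12, 0.24, 0.54, 0.40, 0.00),
    _trait("NL", 6.13, 0.41, 0.71, 0.50, 0.00),
    _trait("LL", 50.39, 28.17, 0.81, 0.70, 0.00),
    _trait("LW", 13.72, 0.94, 0.36, 0.50, 0.00),
    _trait("LA", 509.41, 9073.5, 0.88, 0.80, 0.00),
    _trait("PL", 15.56, 7.43, 0.70, 0.50, 0.00),
    _trait("CG", 7.12, 1.00, 0.68, 0.50, 0.00),
    _trait("NMR", 4.20, 1.07, 0.90, 0.00, 0.55),
    _trait("WMR", 0.11, 0.0008, 0.58, 0.00, 0.65),
    _trait("NPR", 9.84, 14.46, 0.94, 0.00, 0.65),
    _trait("LPR", 9.93, 1.84, 0.97, 0.00, 0.40),
    _trait("IL", 1.02, 0.003, 0.13, 0.05, 0.05),
    _trait("GPR", 18.01, 4.28, 0.76, 0.00, 0.50),
    _trait("WPR", 0.16, 0.003, 0.64, 0.00, 0.85),
    _trait("TY", 0.50, 0.02, 0.80, 0.10, 0.90),
    _trait("DR", 22.41, 10.75, 0.96, 0.00, -0.35),
]


@dataclass
class SimConfig:
    """Study conditions of the emulated trial."""

    n_families: int = 5
    progeny_per_family: int = 52
    n_checks: int = 3
    n_blocks: int = 14
    years: tuple[str, ...] = ("2024", "2025")
    traits: list[TraitSim] = field(default_factory=lambda: list(_DEFAULT_TRAITS))
    beta_veg_sink: float = 0.86
    family_var: float = 0.25        # share of VEG variance between families
    block_var_frac: float = 0.10    # block variance as a fraction of plot error
    year_sd_frac: float = 0.50      # fixed year-offset sd as a fraction of plot error sd
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.family_var < 1:
            raise ValueError("family_var must lie in [0, 1)")
        if abs(self.beta_veg_sink) >= 1:
            raise ValueError("|beta_veg_sink| must be < 1 for a PD latent covariance")
        for t in self.traits:
            if min(t.sigma2_g, t.sigma2_e, t.sigma2_gy) < 0:
                raise ValueError(f"trait {t.name}: negative variance")
            t.unique_share(self.beta_veg_sink)  # raises if loadings inconsistent

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def with_trait(self, name: str, **kw) -> "SimConfig":
        """Copy of the config with one trait's settings replaced."""
        traits = [replace(t, **kw) if t.name == name else t for t in self.traits]
        return replace(self, traits=traits)


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with the field book's genotypes."""

    genotypes: pd.DataFrame          # genotype, family, role, VEG, SINK + g_<trait>
    realized_h2: pd.Series           # trait -> var(g)/(var(g)+s2gy+s2e), tests only
    genetic_corr: pd.DataFrame       # implied genetic correlation matrix
    config: SimConfig

    def genetic_values(self, trait: str) -> pd.Series:
        return self.genotypes.set_index("genotype")[f"g_{trait}"]


def implied_genetic_corr(config: SimConfig) -> pd.DataFrame:
    """Genetic correlation matrix implied by the latent source-sink model."""
    b = config.beta_veg_sink
    names = config.trait_names
    m = len(names)
    C = np.eye(m)
    for i, ti in enumerate(config.traits):
        for j, tj in enumerate(config.traits):
            if i == j:
                continue
            C[i, j] = (ti.loading_veg * tj.loading_veg
                       + ti.loading_sink * tj.loading_sink
                       + b * (ti.loading_veg * tj.loading_sink
                              + ti.loading_sink * tj.loading_veg))
    return pd.DataFrame(C, index=names, columns=names)


def _trait_specs(config: SimConfig) -> list[TraitSpec]:
    try:
        defaults = {t.name: t for t in read_trait_config()}
    except Exception:  # config file unavailable: plain specs
        defaults = {}
    return [defaults.get(t.name, TraitSpec(name=t.name)) for t in config.traits]


def simulate_trial(config: SimConfig | None = None) -> tuple[FieldBook, SimTruth]:
    """Generate a field book plus its ground truth under ``config``.

    Deterministic in (config, config.seed): the same inputs give a
    byte-identical field book.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    beta = config.beta_veg_sink

    checks = [f"C{i + 1}" for i in range(config.n_checks)]
    tests, families = [], []
    for f in range(config.n_families):
        for k in range(config.progeny_per_family):
            tests.append(f"F{f + 1}-{k + 1:03d}")
            families.append(f"F{f + 1}")
    genotypes = checks + tests
    roles = ["check"] * len(checks) + ["test"] * len(tests)
    fam_col = ["-"] * len(checks) + families
    n_geno = len(genotypes)

    # latent structure: family-structured VEG, SINK = beta*VEG + zeta
    fam_means = rng.normal(0.0, np.sqrt(config.family_var), config.n_families)
    veg = np.empty(n_geno)
    veg[:len(checks)] = rng.normal(0.0, 1.0, len(checks))
    within_sd = np.sqrt(1.0 - config.family_var)
    for i, fam in enumerate(families):
        f = int(fam[1:]) - 1
        veg[len(checks) + i] = fam_means[f] + rng.normal(0.0, within_sd)
    sink = beta * veg + rng.normal(0.0, np.sqrt(1.0 - beta ** 2), n_geno)

    g_values = {}
    for t in config.traits:
        lu = np.sqrt(t.unique_share(beta))
        u = rng.normal(0.0, 1.0, n_geno)
        g_values[t.name] = t.mean + np.sqrt(t.sigma2_g) * (
            t.loading_veg * veg + t.loading_sink * sink + lu * u)

    blocks = [f"B{j + 1:02d}" for j in range(config.n_blocks)]
    year_offsets = {t.name: rng.normal(0.0, config.year_sd_frac * np.sqrt(t.sigma2_e),
                                       len(config.years))
                    for t in config.traits}
    records: list[PlotRecord] = []
    for yi, year in enumerate(config.years):
        block_eff = {t.name: rng.normal(
            0.0, np.sqrt(config.block_var_frac * t.sigma2_e), config.n_blocks)
            for t in config.traits}
        gy = {t.name: rng.normal(0.0, np.sqrt(t.sigma2_gy), n_geno)
              for t in config.traits}
        # tests to blocks, uniformly at random, re-randomized each year
        order = rng.permutation(len(tests))
        assignment = {}
        for bj, chunk in enumerate(np.array_split(order, config.n_blocks)):
            for ti in chunk:
                assignment[tests[ti]] = bj
        plot_no = 0
        for bj, block in enumerate(blocks):
            members = checks + [g for g, a in assignment.items() if a == bj]
            for geno in members:
                gi = genotypes.index(geno)
                values = {}
                for t in config.traits:
                    e = rng.normal(0.0, np.sqrt(t.sigma2_e))
                    values[t.name] = (g_values[t.name][gi] + year_offsets[t.name][yi]
                                      + gy[t.name][gi] + block_eff[t.name][bj] + e)
                plot_no += 1
                records.append(PlotRecord(
                    year=year, block=block, plot=f"P{plot_no:04d}",
                    genotype=geno, role=roles[gi], values=values))

    fb = FieldBook(records=records, traits=_trait_specs(config))
    truth_df = pd.DataFrame({"genotype": genotypes, "family": fam_col,
                             "role": roles, "VEG": veg, "SINK": sink})
    for name, g in g_values.items():
        truth_df[f"g_{name}"] = g
    test_mask = truth_df["role"] == "test"
    h2 = {}
    for t in config.traits:
        vg = float(np.var(truth_df.loc[test_mask, f"g_{t.name}"], ddof=1))
        h2[t.name] = vg / (vg + t.sigma2_gy + t.sigma2_e)
    truth = SimTruth(genotypes=truth_df, realized_h2=pd.Series(h2, name="H2"),
                     genetic_corr=implied_genetic_corr(config), config=config)
    logger.info("simulated trial: %d tests, %d checks, %d blocks, %d years (seed %d)",
                len(tests), len(checks), config.n_blocks, len(config.years), config.seed)
    return fb, truth


def recovery_report(truth: SimTruth, *,
                    h2_estimates: pd.Series | dict | None = None,
                    sem_veg_sink_std: float | None = None,
                    selected: list[str] | None = None,
                    yield_trait: str = "TY") -> dict:
    """Estimated-versus-true summary for a simulated trial.

    Collects whatever pipeline outputs are supplied: per-trait H2
    estimates, the standardized vegetative-growth -> sink path from the
    SEM, and the mean true genotypic yield of a selected set relative to
    the test-population mean.
    """
    report: dict = {}
    if h2_estimates is not None:
        est = pd.Series(h2_estimates, dtype=float)
        joint = pd.DataFrame({"true_H2": truth.realized_h2, "est_H2": est}).dropna()
        joint["abs_error"] = (joint["est_H2"] - joint["true_H2"]).abs()
        report["h2"] = joint
        report["h2_mean_abs_error"] = float(joint["abs_error"].mean())
    if sem_veg_sink_std is not None:
        true_beta = truth.config.beta_veg_sink
        report["sem_veg_sink"] = {"true": true_beta, "estimated": sem_veg_sink_std,
                                  "error": sem_veg_sink_std - true_beta}
    if selected is not None:
        g = truth.genetic_values(yield_trait)
        tests = truth.genotypes.loc[truth.genotypes["role"] == "test", "genotype"]
        pop = g.loc[tests]
        chosen = g.loc[[s for s in selected if s in g.index]]
        if chosen.empty:
            raise ValueError("selected genotypes not found in the truth table")
        report["selection"] = {"population_mean": float(pop.mean()),
                               "selected_mean": float(chosen.mean()),
                               "true_differential": float(chosen.mean() - pop.mean())}
    return report
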