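"""End-to-end orchestration of the trial-analysis pipeline.

Stage order: simulate (or ingest) -> adjust -> pool -> genpar -> assoc ->
sem -> select.  Each stage consumes the previous stage's in-memory
outputs, and `run_pipeline` persists every completed stage as tidy CSV/JSON
with content hashes in a manifest.  A single global seed fans out to
per-stage seeds through a stable hash, so toggling one stage does not
shift another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arcbd, associations, genparams, indices, pooling, sem
from .fieldbook import FieldBook, TraitSpec, logger, read_fieldbook, write_results
from .simulate import SimConfig, simulate_trial

STAGE_ORDER = ["simulate", "adjust", "pool", "genpar", "assoc", "sem", "select"]
STAGE_DEPS = {
    "adjust": ["simulate"],  # or an ingested field book
    "pool": ["adjust"],
    "genpar": ["adjust", "pool"],
    "assoc": ["pool"],
    "sem": ["pool"],
    "select": ["pool", "genpar"],
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------- helpers

def adjusted_means_wide(fb: FieldBook, year: str) -> pd.DataFrame:
    """Genotype x trait table of block-adjusted means for one year."""
    cols = {}
    for trait in fb.trait_names:
        tbl = arcbd.adjust_means(fb, year, trait)
        cols[trait] = tbl.set_index("genotype")["adjusted_mean"]
    return pd.DataFrame(cols)


def per_year_adjusted_means(fb: FieldBook) -> dict[str, pd.DataFrame]:
    return {year: adjusted_means_wide(fb, year) for year in fb.meta["years"]}


def stack_years(fb: FieldBook) -> FieldBook:
    """Stack all years into one pseudo-year with year:block composite blocks,
    for the pooled augmented-design ANOVA."""
    from .fieldbook import PlotRecord
    records = [
        PlotRecord(year="pooled", block=f"{r.year}:{r.block}", plot=f"{r.year}:{r.plot}",
                   genotype=r.genotype, role=r.role, values=r.values)
        for r in fb.records
    ]
    return FieldBook(records=records, traits=fb.traits)


def pooled_anova_tables(fb: FieldBook) -> dict[str, arcbd.AnovaTable]:
    stacked = stack_years(fb)
    return {trait: arcbd.arcbd_anova(stacked, "pooled", trait) for trait in fb.trait_names}


def genetic_parameter_table(fb: FieldBook, pooled_means: pd.DataFrame,
                            p_selected: float = 0.05,
                            ga_formula: str = "classical") -> pd.DataFrame:
    """Table of variance components and genetic parameters per trait, using
    the pooled (stacked-years) ANOVA mean squares and the pooled-mean trait
    averages."""
    anovas = pooled_anova_tables(fb)
    rows = []
    for trait in fb.trait_names:
        an = anovas[trait]
        mean = float(pooled_means[trait].mean())
        vc = genparams.variance_components(an.ms_tests, an.ms_residual, mean, trait)
        gp = genparams.genetic_params(vc, p_selected=p_selected, ga_formula=ga_formula)
        rows.append({
            "trait": trait, "mean": mean,
            "sigma2_p": vc.sigma2_p, "sigma2_e": vc.sigma2_e,
            "sigma2_g": vc.sigma2_g if vc.sigma2_g is not None else np.nan,
            "GCV_pct": gp.GCV_pct if gp.GCV_pct is not None else np.nan,
            "PCV_pct": gp.PCV_pct,
            "H2_pct": gp.H2_pct if gp.H2_pct is not None else np.nan,
            "GA": gp.GA if gp.GA is not None else np.nan,
            "GA_pct_of_mean": gp.GA_pct_of_mean if gp.GA_pct_of_mean is not None else np.nan,
            "GCV_cat": gp.categories["GCV"], "PCV_cat": gp.categories["PCV"],
            "H2_cat": gp.categories["H2"],
        })
    return pd.DataFrame(rows)


def genotypic_phenotypic_cov(per_year: dict[str, pd.DataFrame]
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Entry-mean phenotypic (P) and genotypic (G) covariance matrices from
    the genotype x year tables, via the mean-cross-product analogue of the
    variance-component decomposition."""
    years = sorted(per_year)
    y = len(years)
    common = per_year[years[0]].dropna().index
    for yr in years[1:]:
        common = common.intersection(per_year[yr].dropna().index)
    mats = [per_year[yr].loc[common] for yr in years]
    traits = mats[0].columns
    pooled = sum(mats) / y
    P = pooled.cov()
    # interaction cross-products
    resid = [m - pooled - (m.mean() - pooled.mean()) for m in mats]
    g = len(common)
    MSP_gy = sum(r.T @ r for r in resid) / ((g - 1) * (y - 1))
    MSP_g = y * P
    G = (MSP_g - MSP_gy) / y
    return P, pd.DataFrame(G, index=traits, columns=traits)


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-serializable."""

    fieldbook: str | None = None
    trait_config: str | None = None
    sim: SimConfig | None = None
    stages: list[str] = dc_field(default_factory=lambda: list(STAGE_ORDER))
    p_selected: float = 0.05
    si: float = 0.20
    response: str = "TY"
    sem_n: int | None = None       # sample size for the SEM; default = n genotypes
    sh_weights: dict[str, float] | None = None
    mtsi_theta: float = 0.5
    ga_formula: str = "classical"
    seed: int = 42
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


class PipelineConfigError(ValueError):
    pass


def _validate_stages(config: PipelineConfig) -> list[str]:
    stages = [s for s in STAGE_ORDER if s in config.stages]
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")
    enabled = set(stages)
    if "simulate" not in enabled and config.fieldbook is None and "adjust" in enabled:
        raise PipelineConfigError("stage 'adjust' needs either the simulate stage "
                                  "or a fieldbook path")
    for st in stages:
        for dep in STAGE_DEPS.get(st, []):
            if dep == "simulate" and config.fieldbook is not None:
                continue
            if dep not in enabled:
                raise PipelineConfigError(f"stage '{st}' requires stage '{dep}'")
    return stages


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns a manifest: stage -> written files with sha256 content hashes,
    plus a ``results`` entry holding the in-memory stage outputs.
    """
    stages = _validate_stages(config)
    out_root = Path(config.out_dir)
    results: dict = {}
    manifest: dict = {"seed": config.seed, "stages": {}, "results": results}

    def persist(stage: str, tables: dict[str, pd.DataFrame]):
        files = write_results(tables, out_root / stage, seed=config.seed,
                              config={"stage": stage})
        hashed = {}
        for name, path in files.items():
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
            hashed[name] = {"path": path, "sha256": digest}
        manifest["stages"][stage] = hashed

    fb: FieldBook | None = None
    truth = None
    if "simulate" in stages:
        sim_cfg = config.sim or SimConfig()
        sim_cfg = SimConfig(**{**sim_cfg.__dict__,
                               "seed": stage_seed(config.seed, "simulate")}) \
            if config.sim is None else sim_cfg
        fb, truth = simulate_trial(sim_cfg)
        results["truth"] = truth
        persist("simulate", {"fieldbook": fb.to_frame(),
                             "truth": truth.genotypes})
    elif config.fieldbook is not None:
        fb = read_fieldbook(config.fieldbook, config.trait_config)

    if "adjust" in stages:
        assert fb is not None
        per_year = per_year_adjusted_means(fb)
        results["per_year_means"] = per_year
        persist("adjust", {f"adjusted_means_{yr}": tbl.reset_index(names="genotype")
                           for yr, tbl in per_year.items()})

    if "pool" in stages:
        per_year = results["per_year_means"]
        comps, bart_rows = {}, []
        for trait in fb.trait_names:
            comps[trait] = pooling.pool_years(
                {yr: tbl[[trait]].reset_index(names="genotype")
                     .rename(columns={trait: "adjusted_mean"})
                 for yr, tbl in per_year.items()}, trait)
            try:
                samples = [arcbd.check_residuals(fb, yr, trait) for yr in fb.meta["years"]]
                br = pooling.bartlett_test(samples)
                bart_rows.append(dict(trait=trait, statistic=br.statistic,
                                      df=br.df, p=br.p))
            except ValueError as exc:
                logger.warning("Bartlett test skipped for %s: %s", trait, exc)
        pooled = pd.DataFrame({t: c.pooled_means for t, c in comps.items()})
        results["pooled_means"] = pooled
        results["pooled_components"] = comps
        results["bartlett"] = pd.DataFrame(bart_rows)
        persist("pool", {
            "pooled_means": pooled.reset_index(names="genotype"),
            "variance_components": pd.DataFrame(
                [dict(trait=t, sigma2_g=c.sigma2_g, sigma2_gy=c.sigma2_gy,
                      floored=c.negative_g_floored) for t, c in comps.items()]),
            "bartlett": results["bartlett"],
        })

    if "genpar" in stages:
        gp = genetic_parameter_table(fb, results["pooled_means"],
                                     p_selected=config.p_selected,
                                     ga_formula=config.ga_formula)
        results["genetic_parameters"] = gp
        window_counts = genparams.count_in_ideotype_window(results["pooled_means"], fb.traits)
        results["ideotype_counts"] = window_counts
        persist("genpar", {"genetic_parameters": gp,
                           "ideotype_counts": pd.DataFrame(
                               [{"trait": t, "n_in_window": c}
                                for t, c in window_counts.items()])})

    if "assoc" in stages:
        pooled = results["pooled_means"]
        Z = associations.standardize(pooled)
        corr = associations.pearson_matrix(pooled)
        fit = associations.forward_aic(
            Z[config.response], Z.drop(columns=[config.response]))
        fit.cv = associations.cross_validate(
            Z[config.response], Z[list(fit.coefficients["term"])],
            seed=stage_seed(config.seed, "assoc"))
        results["correlations"] = corr
        results["regression"] = fit
        persist("assoc", {
            "correlation_r": corr.r.reset_index(names="trait"),
            "correlation_codes": corr.codes.reset_index(names="trait"),
            "stepwise_ledger": fit.steps,
            "coefficients": fit.coefficients,
            "cv_summary": pd.DataFrame([fit.cv]),
        })

    if "sem" in stages:
        pooled = results["pooled_means"]
        spec = sem.turmeric_sem_spec(gr="GPR" if "GPR" in pooled.columns else "GR")
        S = pooled[spec.observed].cov()
        n = config.sem_n or len(pooled)
        fit = sem.fit_ml(S, n, spec, seed=stage_seed(config.seed, "sem"))
        idxs = sem.fit_indices(S, fit)
        std = sem.standardize_solution(fit)
        results["sem_fit"] = fit
        results["sem_indices"] = idxs
        results["sem_std"] = std
        persist("sem", {
            "parameters": pd.DataFrame({"parameter": fit.theta.index,
                                        "estimate": fit.theta.values,
                                        "se": fit.se.values, "z": fit.z.values}),
            "standardized_paths": std.paths,
            "fit_indices": pd.DataFrame([{**idxs, "chi2": fit.chi2, "df": fit.df,
                                          "p": fit.p, "n": fit.n}]),
        })

    if "select" in stages:
        pooled = results["pooled_means"]
        per_year = results["per_year_means"]
        traits = fb.traits
        rescaled = indices.rescale_traits(pooled, traits)
        fm = indices.factor_analysis(rescaled)
        ideo = fm.project(pd.Series(100.0, index=rescaled.columns))
        res_mgidi = indices.mgidi(fm, ideo, si=config.si)
        res_fai = indices.fai(fm, si=config.si)
        res_mtsi = indices.mtsi(per_year, traits, si=config.si, theta=config.mtsi_theta)
        P, G = genotypic_phenotypic_cov(per_year)
        w = pd.Series(config.sh_weights or 1.0, index=pooled.columns, dtype=float)
        res_sh = indices.smith_hazel(P, G, w, pooled, si=config.si,
                                     p_for_k=config.si)
        gp = results["genetic_parameters"].set_index("trait")
        h2 = (gp["H2_pct"] / 100.0).to_dict()
        all_results = {r.method: r for r in (res_mgidi, res_mtsi, res_fai, res_sh)}
        gains = {m: indices.selection_gains(pooled, r.selected, h2)
                 for m, r in all_results.items()}
        coin = indices.coincidence({m: r.selected for m, r in all_results.items()})
        results["index_results"] = all_results
        results["gains"] = gains
        results["coincidence"] = coin
        score_tbl = pd.DataFrame({m: r.scores for m, r in all_results.items()})
        persist("select", {
            "index_scores": score_tbl.reset_index(names="genotype"),
            "selected": pd.DataFrame({m: pd.Series(sorted(r.selected))
                                      for m, r in all_results.items()}),
            "gains": pd.concat([g.assign(method=m) for m, g in gains.items()]),
            "coincidence": coin.pairwise,
            "venn": pd.DataFrame([{"partition": k, "count": v}
                                  for k, v in sorted(coin.venn_partition_counts.items())]),
        })

    manifest_path = out_root / "manifest.json"
    out_root.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(json.dumps(
        {k: v for k, v in manifest.items() if k != "results"}, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d stages -> %s", len(stages), out_root)
    return manifest


# ---------------------------------------------------------------- report

def render_report(manifest: dict) -> str:
    """Single markdown document summarizing all completed stages."""
    res = manifest.get("results", {})
    lines = ["# Trial analysis report", ""]
    if "per_year_means" in res:
        yrs = sorted(res["per_year_means"])
        n = len(res["per_year_means"][yrs[0]])
        lines += [f"## Adjusted means", "",
                  f"{n} genotypes x {res['per_year_means'][yrs[0]].shape[1]} traits, "
                  f"years {', '.join(yrs)}.", ""]
    if "genetic_parameters" in res:
        lines += ["## Genetic parameters", "",
                  res["genetic_parameters"].round(3).to_markdown(index=False), ""]
    if "correlations" in res:
        corr = res["correlations"]
        lines += ["## Trait correlations", "",
                  corr.r.round(2).to_markdown(), ""]
    if "regression" in res:
        fit = res["regression"]
        lines += ["## Stepwise regression", "",
                  f"Response {fit.response}: adjusted R2 = {fit.adjR2:.3f}, "
                  f"RSE = {fit.RSE:.3f}.", "",
                  fit.coefficients.round(4).to_markdown(index=False), ""]
    if "sem_fit" in res:
        fit = res["sem_fit"]
        idxs = res.get("sem_indices", {})
        lines += ["## Yield-architecture SEM", "",
                  f"chi2 = {fit.chi2:.2f}, df = {fit.df}, p = {fit.p:.3f}, "
                  f"GFI = {idxs.get('GFI', float('nan')):.3f}, "
                  f"SRMR = {idxs.get('SRMR', float('nan')):.3f}.", "",
                  res["sem_std"].paths.round(3).to_markdown(index=False), ""]
    if "index_results" in res:
        lines += ["## Multi-trait selection", ""]
        for m, r in res["index_results"].items():
            lines.append(f"- {m}: {len(r.selected)} genotypes selected; "
                         f"best 5: {', '.join(r.ranking[:5])}")
        lines.append("")
        if "coincidence" in res:
            lines += ["### Coincidence", "",
                      res["coincidence"].pairwise.round(1).to_markdown(index=False), "",
                      f"Common to all methods: "
                      f"{len(res['coincidence'].all_methods_common)} genotypes.", ""]
    if len(lines) <= 2:
        lines.append("(no completed stages)")
    return "\n".join(lines)
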