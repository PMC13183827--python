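# turmsel

Quantitative-genetics analysis of **augmented-design half-sib trials** in
vegetatively propagated crops, built around the yield architecture of
turmeric (*Curcuma longa* L.). Turmeric is almost exclusively clonally
propagated, so rare seed-derived half-sib progenies (same maternal parent,
open pollination) are a precious source of new recombination. Evaluating a
few hundred unreplicated seedling progenies alongside a handful of
replicated check varieties calls for the augmented randomized complete
block design (ARCBD) and a chain of analyses this package implements end to
end:

1. **Federer block adjustment** — block effects from the replicated checks,
   `b_j = x̄_checks,j − x̄_checks`, and adjusted test means `V_i = u_i − b_j`;
   partitioned ARCBD ANOVA (checks / tests / tests-vs-checks), CD, SE(m), CV%.
2. **Across-year pooling** — Bartlett's homogeneity test, then a two-way
   genotype × year analysis of the adjusted means with years fixed and
   genotypes random: `σ̂²_gy = MS_GY`, `σ̂²_g = (MS_G − MS_GY)/y`.
3. **Genetic parameters** — `σ²_g = σ²_p − σ²_e` from the ANOVA mean
   squares, `GCV = 100·σ_g/x̄`, `PCV = 100·σ_p/x̄`, broad-sense
   `H² = σ²_g/σ²_p`, and genetic advance `GA = k·σ_p·H²` with
   k = φ(z_p)/p the truncation-selection intensity (k = 2.063 at 5%).
4. **Trait associations** — Pearson correlations with significance codes,
   forward-AIC multiple regression on standardized adjusted means, VIF
   diagnostics, repeated 10-fold cross-validation.
5. **Yield-architecture SEM** — a fixed hierarchical source–sink
   structural-equation model: latent vegetative growth (leaf width, leaf
   number, petiole length) drives a second-order rhizome-sink factor
   (first-order primary- and mother-rhizome factors over NPR, GPR, NMR),
   and both predict total yield. Normal-theory ML on the sample covariance
   (RAM parametrization, analytic gradient, multistart quasi-Newton with a
   trust-region polish), χ²/GFI/SRMR, standardized solution, Heywood flags.
   The model has 7·8/2 − 19 = **9 degrees of freedom**.
6. **Multi-trait selection** — MGIDI, MTSI, FAI and Smith–Hazel
   (`b = P⁻¹Gw`) indices at 20% intensity, per-trait selection gains
   `SG% = 100·H²·(x̄_sel − x̄)/x̄`, and coincidence/Venn analysis of the
   selected sets.
7. **Synthetic trials** — a generator that emulates the whole study (5
   half-sib families × 52 progenies, 3 checks, 14 blocks, 2 years) from a
   latent source–sink model with known genotypic values, so every stage is
   testable with ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
trial and write tidy CSVs under `results/`:

```bash
python analysis/01_simulate_trial.py --seed 1
python analysis/02_adjust_and_pool.py
python analysis/03_genetic_parameters.py
python analysis/04_trait_associations.py
python analysis/05_sem_yield_architecture.py
python analysis/06_selection_indices.py
```

With seed 1 this prints, among other things:

```
Simulated trial (seed 1): 260 test progenies, 3 checks, 14 blocks, years 2024, 2025.
Bartlett homogeneity held (p > 0.05) for 15/17 traits, supporting the pooled analysis.
High broad-sense heritability (>60%) for 15 of 17 traits: PH, NT, NL, ...
Model df = 9 (28 moments - 19 free parameters)
chi2 = 14.71, df = 9, p = 0.099; GFI = 0.985, SRMR = 0.034
MGIDI: selected 53 genotypes; predicted TY gain +16.9%
MGIDI realized response (true genotypic TY): selected mean 0.616 vs population 0.503 kg/plant.
```

Reading the output: error variances are homogeneous across the two years,
so pooling is justified; most traits are strongly heritable, so phenotypic
selection is effective; the SEM fits (non-significant χ² on df = 9, GFI
near 1, SRMR near 0), supporting the source→sink→yield cascade; and the
MGIDI-selected 20% (53 of 263 genotypes) genuinely carries a higher true
genotypic yield than the population (0.616 vs 0.503 kg/plant) — a check
only a simulator with known truth can make.

The same pipeline runs on real field books
(`turmsel pipeline --fieldbook FB.csv --traits traits.yml --seed 42 --out DIR`,
or `turmsel.pipeline.run_pipeline` from Python): a CSV with columns
`year, block, plot, genotype, role` plus one column per trait, and a YAML
trait config (label, units, direction, optional ideotype window).

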