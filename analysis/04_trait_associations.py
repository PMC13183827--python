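"""Trait associations driving total yield.

Pearson correlations among the 17 traits on standardized pooled adjusted
means, forward-AIC multiple regression of total yield (TY) on the other
traits with VIF diagnostics, and repeated 10-fold cross-validation of
the final model.  Writes correlation, step-ledger, coefficient and CV
tables under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from turmsel import associations
from turmsel.fieldbook import write_results

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 42) -> None:
    pooled = pd.read_csv(ROOT / "results" / "adjust_pool" / "pooled_means.csv",
                         index_col="genotype")
    corr = associations.pearson_matrix(pooled)
    Z = associations.standardize(pooled)
    fit = associations.forward_aic(Z["TY"], Z.drop(columns=["TY"]))
    fit.cv = associations.cross_validate(Z["TY"], Z[list(fit.coefficients["term"])],
                                         k=10, repeats=10, seed=seed)

    write_results({
        "correlation_r": corr.r.reset_index(names="trait"),
        "correlation_p": corr.p.reset_index(names="trait"),
        "correlation_codes": corr.codes.reset_index(names="trait"),
        "stepwise_ledger": fit.steps,
        "coefficients": fit.coefficients,
        "cv_summary": pd.DataFrame([fit.cv]),
    }, ROOT / "results" / "associations", seed=seed)

    ty_r = corr.r["TY"].drop("TY").sort_values(ascending=False)
    print("Strongest correlates of total yield:")
    print(ty_r.head(5).round(2).to_string())
    print(f"\nForward-AIC model: {' + '.join(fit.coefficients['term'])}")
    print(f"adjusted R2 = {fit.adjR2:.3f}, RSE = {fit.RSE:.3f}; "
          f"VIF range {fit.coefficients['vif'].min():.2f}-"
          f"{fit.coefficients['vif'].max():.2f}")
    print(f"CV (10-fold x 10): RMSE {fit.cv['rmse_mean']:.3f} +/- {fit.cv['rmse_sd']:.3f}, "
          f"R2 {fit.cv['r2_mean']:.3f} +/- {fit.cv['r2_sd']:.3f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    main(**vars(ap.parse_args()))
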