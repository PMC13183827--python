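"""Variance components and genetic parameters per trait.

Runs the pooled (stacked-years) augmented-design ANOVA, derives
sigma2_p/sigma2_e/sigma2_g, GCV/PCV, broad-sense heritability, genetic
advance at 5% selected, trial precision statistics (CD, SE(m), CV%) and
the ideotype-window counts.  Writes a Table-3-style CSV under results/.
"""

from pathlib import Path

import pandas as pd

from turmsel import arcbd
from turmsel.fieldbook import read_fieldbook, write_results
from turmsel.genparams import count_in_ideotype_window
from turmsel.pipeline import genetic_parameter_table, pooled_anova_tables

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    fb = read_fieldbook(ROOT / "results" / "data" / "fieldbook.csv")
    pooled = pd.read_csv(ROOT / "results" / "adjust_pool" / "pooled_means.csv",
                         index_col="genotype")
    gp = genetic_parameter_table(fb, pooled, p_selected=0.05)

    anovas = pooled_anova_tables(fb)
    prec_rows = []
    for trait, an in anovas.items():
        ps = arcbd.precision_stats(an)
        prec_rows.append(dict(trait=trait, CD=ps.CD, SEm=ps.SEm, CV_pct=ps.CV_pct,
                              **{f"sed_{k}": v for k, v in ps.sed.items()}))
    precision = pd.DataFrame(prec_rows)

    counts = count_in_ideotype_window(pooled, fb.traits)
    count_tbl = pd.DataFrame([{"trait": t, "n_in_window": c} for t, c in counts.items()])

    write_results({"genetic_parameters": gp, "precision": precision,
                   "ideotype_counts": count_tbl},
                  ROOT / "results" / "genetic_parameters")

    high_h2 = gp.loc[gp["H2_pct"] > 60, "trait"].tolist()
    print(gp[["trait", "mean", "sigma2_p", "sigma2_g", "GCV_pct", "PCV_pct",
              "H2_pct", "GA_pct_of_mean"]].round(2).to_string(index=False))
    print(f"\nHigh broad-sense heritability (>60%) for {len(high_h2)} of "
          f"{len(gp)} traits: {', '.join(high_h2)}")
    print(f"Ideotype-window counts: {counts}")


if __name__ == "__main__":
    main()
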