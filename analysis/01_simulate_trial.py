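"""Generate the working dataset: a two-year augmented-design half-sib
turmeric trial (5 maternal families x 52 progenies, 3 checks replicated
in 14 blocks) with known ground truth.

Writes results/data/fieldbook.csv and truth.csv.  Run this first; the
later numbered scripts read its output.
"""

import argparse
from pathlib import Path

from turmsel.fieldbook import write_fieldbook, write_results
from turmsel.simulate import SimConfig, simulate_trial

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed)
    fb, truth = simulate_trial(cfg)
    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_fieldbook(fb, out / "fieldbook.csv")
    write_results({"truth": truth.genotypes}, out, seed=seed,
                  config={"n_tests": fb.meta["n_tests"]})
    meta = fb.meta
    print(f"Simulated trial (seed {seed}): {meta['n_tests']} test progenies, "
          f"{len(meta['checks'])} checks, {meta['n_blocks']} blocks, "
          f"years {', '.join(meta['years'])}.")
    print(f"Field book: {out / 'fieldbook.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
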