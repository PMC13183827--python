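import numpy as np
import pandas as pd
import pytest

from turmsel.fieldbook import FieldBook, PlotRecord, TraitSpec
from turmsel.simulate import SimConfig, TraitSim, simulate_trial


def make_fieldbook(years=("Y1",), n_blocks=4, checks=("C1", "C2", "C3"),
                   n_tests=12, traits=("T1",), seed=0, value_fn=None):
    """Programmatic tiny ARCBD field book; value_fn(year, block, genotype,
    trait, rng) -> float overrides the default random values."""
    rng = np.random.default_rng(seed)
    tests = [f"G{i + 1:02d}" for i in range(n_tests)]
    records = []
    plot = 0
    for year in years:
        order = rng.permutation(n_tests)
        assign = {tests[t]: b for b, chunk in
                  enumerate(np.array_split(order, n_blocks)) for t in chunk}
        for b in range(n_blocks):
            block = f"B{b + 1}"
            members = list(checks) + [g for g, bb in assign.items() if bb == b]
            for geno in members:
                plot += 1
                vals = {}
                for tr in traits:
                    if value_fn is not None:
                        vals[tr] = value_fn(year, block, geno, tr, rng)
                    else:
                        vals[tr] = float(rng.normal(10, 2))
                records.append(PlotRecord(year=year, block=block, plot=f"P{plot}",
                                          genotype=geno,
                                          role="check" if geno in checks else "test",
                                          values=vals))
    return FieldBook(records=records, traits=[TraitSpec(name=t) for t in traits])


@pytest.fixture(scope="session")
def small_sim():
    """A reduced two-year simulated trial (cheap enough for many tests)."""
    cfg = SimConfig(n_families=3, progeny_per_family=20, seed=11)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions (5 families x 52 progenies, 14 blocks, 2 years)."""
    return simulate_trial(SimConfig(seed=1))


def tiny_csv(tmp_path, drop_check_row=False, drop_column=None, bad_cell=False):
    """The 2-block, 2-check, 2-test field book used in the I/O examples."""
    rows = [
        "year,block,plot,genotype,role,PH,TY",
        "Y1,B1,P1,C1,check,100,0.5",
        "Y1,B1,P2,C2,check,90,0.4",
        "Y1,B1,P3,G01,test,95,0.45",
        "Y1,B2,P4,C1,check,102,0.52",
        "Y1,B2,P5,C2,check,88,0.38",
        "Y1,B2,P6,G02,test,97,0.55",
    ]
    if drop_check_row:
        rows = [r for r in rows if not r.startswith("Y1,B2,P5")]
    if bad_cell:
        rows[3] = "Y1,B1,P3,G01,test,ninety-five,0.45"
    text = "\n".join(rows) + "\n"
    if drop_column is not None:
        import csv, io
        reader = list(csv.reader(io.StringIO(text)))
        idx = reader[0].index(drop_column)
        text = "\n".join(",".join(c for i, c in enumerate(r) if i != idx)
                         for r in reader) + "\n"
    path = tmp_path / "fb.csv"
    path.write_text(text)
    cfg = tmp_path / "traits.yml"
    cfg.write_text(
        "PH: {label: Plant height, units: cm, direction: increase, ideotype: [80, 110]}\n"
        "TY: {label: Total yield, units: kg, direction: increase, ideotype: null}\n")
    return path, cfg
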