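"""Field-book data model and I/O for augmented-design trials.

An augmented randomized complete block design (ARCBD) replicates a small
set of check varieties in every block while each unreplicated test entry
(here: a half-sib seedling progeny) occurs in exactly one block per year.
The checks carry all the information about block effects and experimental
error; the tests carry the genetic variation of interest.

The plot-level field book is the single input of the whole pipeline.  It
is a plain CSV with the mandatory columns ``year, block, plot, genotype,
role`` plus one numeric column per configured trait; the trait roster
itself lives in a small YAML file mapping trait code -> label/units/
direction/ideotype window.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("turmsel")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

MANDATORY_COLUMNS = ("year", "block", "plot", "genotype", "role")


class SchemaError(ValueError):
    """A mandatory column or trait column is missing from the field book."""


class DesignValidationError(ValueError):
    """The field book violates the ARCBD replication structure."""


class TraitParseError(ValueError):
    """A trait cell could not be parsed as a number."""


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait: code, free-text label, units, desired direction
    of selection and an optional closed ideotype window [lo, hi]."""

    name: str
    label: str = ""
    units: str = ""
    direction: str = "increase"
    ideotype_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"trait {self.name}: direction must be increase/decrease")
        if self.ideotype_window is not None:
            lo, hi = self.ideotype_window
            if not lo <= hi:
                raise ValueError(f"trait {self.name}: ideotype window lo > hi")


@dataclass(frozen=True)
class PlotRecord:
    """One plot: its position in the design and the trait values observed
    on it (missing cells stored as NaN)."""

    year: str
    block: str
    plot: str
    genotype: str
    role: str  # "check" | "test"
    values: Mapping[str, float] = field(default_factory=dict)


@dataclass
class FieldBook:
    """A validated collection of plot records plus the trait roster."""

    records: list[PlotRecord]
    traits: list[TraitSpec]

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def meta(self) -> dict:
        df = self.to_frame()
        checks = sorted(df.loc[df["role"] == "check", "genotype"].unique())
        tests = sorted(df.loc[df["role"] == "test", "genotype"].unique())
        return {
            "n_blocks": df["block"].nunique(),
            "checks": checks,
            "n_tests": len(tests),
            "years": sorted(df["year"].unique()),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "year": r.year, "block": r.block, "plot": r.plot,
                "genotype": r.genotype, "role": r.role,
            }
            for t in self.trait_names:
                row[t] = r.values.get(t, math.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + self.trait_names)


def default_trait_config_path() -> Path:
    return Path(str(resources.files("turmsel").joinpath("config/turmeric_traits.yml")))


def read_trait_config(path: str | Path | None = None) -> list[TraitSpec]:
    """Read the YAML trait roster (trait code -> label/units/direction/ideotype)."""
    path = Path(path) if path is not None else default_trait_config_path()
    raw = yaml.safe_load(path.read_text())
    traits = []
    seen: set[str] = set()
    for name, cfg in raw.items():
        if name in seen:
            raise ValueError(f"duplicate trait code {name}")
        seen.add(name)
        cfg = cfg or {}
        window = cfg.get("ideotype")
        traits.append(TraitSpec(
            name=str(name),
            label=str(cfg.get("label", "")),
            units=str(cfg.get("units", "")),
            direction=str(cfg.get("direction", "increase")),
            ideotype_window=tuple(float(v) for v in window) if window else None,
        ))
    return traits


def validate_design(df: pd.DataFrame, checks: Sequence[str]) -> None:
    """Enforce the ARCBD replication invariants.

    Every check appears exactly once in every (year, block); every test
    appears in exactly one block per year.
    """
    problems = []
    for year, ydf in df.groupby("year", sort=True):
        blocks = sorted(ydf["block"].unique())
        for block in blocks:
            present = ydf.loc[ydf["block"] == block, "genotype"]
            counts = present.value_counts()
            for chk in checks:
                if counts.get(chk, 0) != 1:
                    problems.append((year, block, chk))
        tests = ydf[ydf["role"] == "test"]
        per_geno_blocks = tests.groupby("genotype")["block"].nunique()
        multi = per_geno_blocks[per_geno_blocks > 1]
        for g in multi.index:
            raise DesignValidationError(
                f"test genotype {g} appears in more than one block of year {year}")
        dup = tests.groupby(["genotype", "block"]).size()
        if (dup > 1).any():
            g, b = dup[dup > 1].index[0]
            raise DesignValidationError(
                f"test genotype {g} has multiple plots in block {b} of year {year}")
    if problems:
        listed = "; ".join(f"(year {y}, block {b}, check {c})" for y, b, c in problems[:10])
        raise DesignValidationError(
            f"{len(problems)} (year, block, check) cells without exactly one check plot: {listed}")
    overlap = set(df.loc[df["role"] == "check", "genotype"]) & set(
        df.loc[df["role"] == "test", "genotype"])
    if overlap:
        raise DesignValidationError(f"labels used as both check and test: {sorted(overlap)}")


def read_fieldbook(path: str | Path, trait_config: str | Path | None = None) -> FieldBook:
    """Read and validate a plot-level field-book CSV.

    Missing trait cells are kept as NaN; non-numeric cells raise
    :class:`TraitParseError` with the offending row number (1-based,
    excluding the header).
    """
    traits = read_trait_config(trait_config)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"field book is missing mandatory column '{col}'")
    for t in traits:
        if t.name not in df.columns:
            raise SchemaError(f"field book is missing trait column '{t.name}'")
    bad_roles = set(df["role"].unique()) - {"check", "test"}
    if bad_roles:
        raise SchemaError(f"role column contains values other than check/test: {sorted(bad_roles)}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        values = {}
        for t in traits:
            cell = getattr(row, t.name).strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                values[t.name] = math.nan
                continue
            try:
                values[t.name] = float(cell)
            except ValueError as exc:
                raise TraitParseError(
                    f"row {i}: trait {t.name} cell '{cell}' is not numeric") from exc
        records.append(PlotRecord(
            year=row.year, block=row.block, plot=row.plot,
            genotype=row.genotype, role=row.role, values=values))

    fb = FieldBook(records=records, traits=traits)
    df_full = fb.to_frame()
    checks = sorted(df_full.loc[df_full["role"] == "check", "genotype"].unique())
    validate_design(df_full, checks)
    meta = fb.meta
    logger.info("read field book: %d plots, %d tests, %d checks, %d blocks, years %s",
                len(records), meta["n_tests"], len(meta["checks"]),
                meta["n_blocks"], ",".join(meta["years"]))
    return fb


def write_fieldbook(fb: FieldBook, path: str | Path) -> None:
    """Write the field book back to CSV (12 significant digits)."""
    df = fb.to_frame()
    df.to_csv(path, index=False, float_format="%.12g")


def _config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config, sort_keys=True, default=str) if config else ""
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path, *,
                  seed: int | None = None, config: Mapping | None = None) -> dict:
    """Write each named result table as a tidy CSV plus one JSON run summary.

    Returns a manifest mapping names to file paths.  CSV floats are
    formatted at 12 significant digits so a read-back round-trips the
    values for all practical purposes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in tables.items():
        dest = out / f"{name}.csv"
        table.to_csv(dest, index=False, float_format="%.12g")
        manifest[name] = str(dest)
    summary = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "python": sys.version.split()[0],
        "tables": sorted(tables),
    }
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest["run_summary"] = str(summary_path)
    logger.info("wrote %d result tables to %s", len(tables), out)
    return manifest
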