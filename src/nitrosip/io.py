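"""Reading, validating and writing the tidy interchange tables.

Three long-format CSV/TSV tables describe one experiment:

``chemistry``  soil, condition, isotope, replicate, day, nh4, nox, ph
``abundance``  soil, condition, isotope, replicate, day, guild, copies
``gradient``   soil, condition, isotope, replicate, microcosm_id, guild,
               fraction_index, buoyant_density, copies

Guilds are AOA / AOB / comammox; isotopes 12C / 13C (day-0 rows, sampled
before CO2 amendment, may carry "none").  Validation reports row-level
diagnostics; all writers round-trip exactly through their readers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synthetic import GUILDS, SimConfig, SyntheticDataset

CHEM_COLUMNS = ["soil", "condition", "isotope", "replicate", "day", "nh4", "nox", "ph"]
ABUND_COLUMNS = ["soil", "condition", "isotope", "replicate", "day", "guild", "copies"]
GRAD_COLUMNS = [
    "soil", "condition", "isotope", "replicate", "microcosm_id",
    "guild", "fraction_index", "buoyant_density", "copies",
]
VALID_ISOTOPES = {"12C", "13C", "none"}
VALID_CONDITIONS = {"native", "modified"}


class DatasetError(ValueError):
    """Schema or integrity violation in an input table."""


@dataclass
class Dataset:
    """Validated in-memory experiment: the three tidy tables + design."""

    chemistry: pd.DataFrame
    abundance: pd.DataFrame
    gradient: pd.DataFrame

    def __post_init__(self) -> None:
        self.chemistry = _check_table(self.chemistry, CHEM_COLUMNS, "chemistry")
        self.abundance = _check_table(self.abundance, ABUND_COLUMNS, "abundance")
        self.gradient = _check_table(self.gradient, GRAD_COLUMNS, "gradient")
        _check_values(self.chemistry, "chemistry", {"nh4": 0.0, "nox": 0.0})
        _check_values(self.abundance, "abundance", {"copies": 0.0})
        _check_values(self.gradient, "gradient", {"copies": 0.0, "buoyant_density": 1e-9})
        for name, df in (("abundance", self.abundance), ("gradient", self.gradient)):
            bad = ~df.guild.isin(GUILDS)
            if bad.any():
                row = df.index[bad][0]
                raise DatasetError(
                    f"{name} row {row}: unknown guild {df.loc[row, 'guild']!r} "
                    f"(expected one of {GUILDS})"
                )
        for name, df in (
            ("chemistry", self.chemistry),
            ("abundance", self.abundance),
            ("gradient", self.gradient),
        ):
            bad = ~df.isotope.astype(str).isin(VALID_ISOTOPES)
            if bad.any():
                row = df.index[bad][0]
                raise DatasetError(f"{name} row {row}: unknown isotope {df.loc[row, 'isotope']!r}")
            bad = ~df.condition.astype(str).isin(VALID_CONDITIONS)
            if bad.any():
                row = df.index[bad][0]
                raise DatasetError(
                    f"{name} row {row}: unknown condition {df.loc[row, 'condition']!r}"
                )
        # referential integrity: every gradient soil x condition must be in the design
        design = set(map(tuple, self.abundance[["soil", "condition"]].drop_duplicates().values))
        grad_keys = set(map(tuple, self.gradient[["soil", "condition"]].drop_duplicates().values))
        orphans = grad_keys - design
        if orphans:
            raise DatasetError(f"gradient rows reference unknown microcosms: {sorted(orphans)}")

    @property
    def soils(self) -> list[str]:
        return sorted(self.abundance.soil.unique())

    @property
    def days(self) -> list[int]:
        return sorted(self.chemistry.day.unique())


def _check_table(df: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DatasetError(f"{name} table is missing column(s) {missing}")
    return df.reset_index(drop=True)


def _check_values(df: pd.DataFrame, name: str, minima: dict[str, float]) -> None:
    for col, lo in minima.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo)
        if bad.any():
            row = df.index[bad][0]
            raise DatasetError(
                f"{name} row {row}: invalid {col}={df.loc[row, col]!r} (must be >= {lo})"
            )


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=delimiter)


def read_dataset(
    chemistry_path: str | Path,
    abundance_path: str | Path,
    gradient_path: str | Path,
    delimiter: str | None = None,
) -> Dataset:
    """Load and validate the three tables (CSV by default, TSV by suffix)."""
    return Dataset(
        _read_table(chemistry_path, delimiter),
        _read_table(abundance_path, delimiter),
        _read_table(gradient_path, delimiter),
    )


def write_dataset(dataset: Dataset | SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the three tables (plus ground truth/config for synthetic data).

    Returns the mapping of artifact name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("chemistry", "abundance", "gradient"):
        p = outdir / f"{name}.csv"
        getattr(dataset, name).to_csv(p, index=False)
        paths[name] = p
    if isinstance(dataset, SyntheticDataset):
        p = outdir / "ground_truth.json"
        p.write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
        paths["ground_truth"] = p
        p = outdir / "sim_config.json"
        p.write_text(json.dumps(dataset.config.to_dict(), indent=2, sort_keys=True))
        paths["sim_config"] = p
    return paths


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration, echoed verbatim into every output artifact."""

    heavy_threshold: float = 1.725  # g ml-1
    delta_min: float = 0.005  # g ml-1
    alpha: float = 0.05
    ttest_variant: str = "pooled"  # or "welch"
    hours: float = 720.0  # incubation duration for contribution arithmetic
    copies_per_cell: float = 1.0
    activities: tuple[tuple[str, float], ...] = (("AOA", 2.6), ("AOB", 23.0), ("comammox", 2.6))
    growth_method: str = "sip"  # "sip" | "qpcr" feeding the apportionment
    subtract_12c: bool = False
    final_day: int | None = None  # default: last sampled day
    seed: int = 0

    def activity_map(self) -> dict[str, float]:
        return dict(self.activities)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["activities"] = dict(self.activities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "activities" in d and isinstance(d["activities"], dict):
            d["activities"] = tuple(sorted(d["activities"].items()))
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
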