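"""Synthetic soil-microcosm generator for ammonia-oxidizer SIP experiments.

Emulates a pH-perturbation microcosm study: several soils, each incubated at
native and modified pH under ``12C``- or ``13C``-CO2 headspace, destructively
sampled over a 30-day course.  Three guilds of ammonia oxidizers (AOA, AOB,
comammox, tracked by their *amoA* gene copies) grow or decline, oxidize
ammonium to NOx-, acidify the soil against its buffer capacity, and — when
growing autotrophically under 13C — shift their DNA to heavier buoyant
densities in a CsCl gradient.

The generator has a fully known ground truth (per-guild growth, labeled
fractions, oxidized N), which downstream estimators are tested against.
Dynamics are daily discrete-time updates; measurement error is multiplicative
lognormal with a configurable coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GUILDS = ("AOA", "AOB", "comammox")
CONDITIONS = ("native", "modified")
ISOTOPES = ("12C", "13C")

#: µg N carried by 1 fmol NH3 (1e-15 mol x 14 g mol-1 N x 1e6 µg g-1)
UG_N_PER_FMOL_NH3 = 14e-9


def _require_finite(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return v


def _require_nonneg(name: str, value: float) -> float:
    v = _require_finite(name, value)
    if v < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")
    return v


@dataclass(frozen=True)
class GuildParams:
    """Parameters of one ammonia-oxidizer guild in one soil.

    Growth rates are per day and may be negative (population decline).
    ``autotroph_fraction`` is the fraction of net growth that assimilates
    13C-CO2 (and hence becomes gradient-detectable); ``per_cell_activity``
    is the ammonia-oxidation rate per cell in fmol NH3 cell-1 h-1.
    """

    guild_name: str
    initial_abundance: float  # amoA copies g-1 dry soil
    growth_rate_native: float  # d-1
    growth_rate_modified: float  # d-1
    autotroph_fraction: float = 1.0
    gc_content: float = 0.5
    amoa_copies_per_cell: float = 1.0
    per_cell_activity: float = 2.6  # fmol NH3 cell-1 h-1

    def __post_init__(self) -> None:
        _require_nonneg("initial_abundance", self.initial_abundance)
        _require_finite("growth_rate_native", self.growth_rate_native)
        _require_finite("growth_rate_modified", self.growth_rate_modified)
        if not 0.0 <= _require_finite("autotroph_fraction", self.autotroph_fraction) <= 1.0:
            raise ValueError(f"autotroph_fraction must be in [0, 1], got {self.autotroph_fraction}")
        if not 0.0 < _require_finite("gc_content", self.gc_content) < 1.0:
            raise ValueError(f"gc_content must be in (0, 1), got {self.gc_content}")
        if _require_finite("amoa_copies_per_cell", self.amoa_copies_per_cell) < 1:
            raise ValueError(f"amoa_copies_per_cell must be >= 1, got {self.amoa_copies_per_cell}")
        if _require_finite("per_cell_activity", self.per_cell_activity) <= 0:
            raise ValueError(f"per_cell_activity must be > 0, got {self.per_cell_activity}")

    def growth_rate(self, condition: str) -> float:
        if condition == "native":
            return self.growth_rate_native
        if condition == "modified":
            return self.growth_rate_modified
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


@dataclass(frozen=True)
class SoilScenario:
    """Chemistry and guild parameterization of one soil."""

    soil_id: str
    native_ph: float
    modified_ph: float
    mineralization_rate: float  # µg N g-1 d-1
    buffer_capacity: float  # µg N g-1 per pH unit
    initial_nh4: float  # µg N g-1
    initial_nox: float  # µg N g-1
    guilds: tuple[GuildParams, ...]

    def __post_init__(self) -> None:
        for name in ("native_ph", "modified_ph"):
            ph = _require_finite(name, getattr(self, name))
            if not 3.0 <= ph <= 9.0:
                raise ValueError(f"{name} must be in [3, 9], got {ph}")
        _require_nonneg("mineralization_rate", self.mineralization_rate)
        if _require_finite("buffer_capacity", self.buffer_capacity) <= 0:
            raise ValueError(f"buffer_capacity must be > 0, got {self.buffer_capacity}")
        _require_nonneg("initial_nh4", self.initial_nh4)
        _require_nonneg("initial_nox", self.initial_nox)
        object.__setattr__(self, "guilds", tuple(self.guilds))
        names = [g.guild_name for g in self.guilds]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate guild names in scenario {self.soil_id}: {names}")

    def initial_ph(self, condition: str) -> float:
        return self.native_ph if condition == "native" else self.modified_ph


@dataclass(frozen=True)
class SimConfig:
    """Design and noise configuration of the simulated experiment.

    The buoyant-density model is a Schildkraut-type linear relation:
    an unlabeled population bands at ``bd_intercept + bd_gc_slope * GC``,
    and full 13C labeling shifts it heavier by ``max_label_shift``.
    Fraction 1 is the heaviest (bottom of the tube); densities decrease
    with fraction index.
    """

    replicates: int = 3
    sample_days: tuple[int, ...] = (0, 15, 30)
    qpcr_cv: float = 0.2
    chem_cv: float = 0.1
    n_fractions: int = 15
    quantified_fractions: tuple[int, int] = (2, 14)
    density_min: float = 1.66
    density_max: float = 1.76
    density_sd: float = 0.008
    bd_intercept: float = 1.66
    bd_gc_slope: float = 0.098
    max_label_shift: float = 0.036
    atom_fraction_excess: float = 1.0
    nh4_limit: float = 1.0  # µg N g-1 below which growth halts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.n_fractions < 3:
            raise ValueError(f"n_fractions must be >= 3, got {self.n_fractions}")
        if not self.density_min < self.density_max:
            raise ValueError("density_min must be < density_max")
        for name in ("qpcr_cv", "chem_cv"):
            if _require_finite(name, getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.quantified_fractions
        if not (1 <= lo <= hi <= self.n_fractions):
            raise ValueError(f"quantified_fractions {self.quantified_fractions} outside 1..{self.n_fractions}")
        _require_nonneg("density_sd", self.density_sd)
        _require_nonneg("max_label_shift", self.max_label_shift)
        object.__setattr__(self, "sample_days", tuple(int(d) for d in self.sample_days))

    def fraction_densities(self) -> np.ndarray:
        """Bin-center buoyant density of each fraction, heaviest first."""
        width = (self.density_max - self.density_min) / self.n_fractions
        idx = np.arange(self.n_fractions)
        return self.density_max - (idx + 0.5) * width

    def fraction_edges(self) -> np.ndarray:
        """Density bin edges, descending, length n_fractions + 1."""
        return np.linspace(self.density_max, self.density_min, self.n_fractions + 1)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# dynamics


def simulate_dynamics(scenario: SoilScenario, condition: str, config: SimConfig) -> pd.DataFrame:
    """Daily discrete-time trajectory of one soil x pH-condition microcosm.

    Each day, guilds growing while NH4+ exceeds ``config.nh4_limit``
    multiply by ``exp(rate)``; the N oxidized is the lesser of the
    available pool (NH4+ plus that day's mineralization) and the guilds'
    aggregate oxidation capacity; NH4+, NOx- and pH are updated and pools
    clipped at zero.  Oxidation is attributed to guilds in proportion to
    their capacity, giving a per-guild ground-truth contribution.

    Returns a frame with one row per day (0..max sample day) and columns
    ``nh4``, ``nox``, ``ph`` plus per-guild ``abundance_*``, ``labeled_*``
    (13C-labeled copies, semiconservative approximation) and cumulative
    ``oxidized_*`` (µg N g-1).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    n_days = max(config.sample_days)
    nh4 = scenario.initial_nh4
    nox = scenario.initial_nox
    ph = scenario.initial_ph(condition)
    abund = {g.guild_name: g.initial_abundance for g in scenario.guilds}
    labeled = {g.guild_name: 0.0 for g in scenario.guilds}
    oxidized = {g.guild_name: 0.0 for g in scenario.guilds}

    rows = [_snapshot(0, nh4, nox, ph, abund, labeled, oxidized)]
    for day in range(1, n_days + 1):
        # oxidation capacity of the standing populations, µg N g-1 d-1
        cap = {}
        for g in scenario.guilds:
            cells = abund[g.guild_name] / g.amoa_copies_per_cell
            cap[g.guild_name] = cells * g.per_cell_activity * 24.0 * UG_N_PER_FMOL_NH3
        total_cap = sum(cap.values())
        available = nh4 + scenario.mineralization_rate
        ox = min(available, total_cap)
        for g in scenario.guilds:
            if total_cap > 0:
                oxidized[g.guild_name] += ox * cap[g.guild_name] / total_cap
        # growth applies while substrate is above the limitation threshold
        if nh4 > config.nh4_limit:
            for g in scenario.guilds:
                rate = g.growth_rate(condition)
                old = abund[g.guild_name]
                new = old * math.exp(rate)
                if new > old:
                    labeled[g.guild_name] += g.autotroph_fraction * (new - old)
                else:  # decline removes labeled and unlabeled copies alike
                    labeled[g.guild_name] *= math.exp(rate)
                abund[g.guild_name] = new
        nh4 = max(0.0, nh4 + scenario.mineralization_rate - ox)
        nox = max(0.0, nox + ox)
        ph = max(0.0, ph - ox / scenario.buffer_capacity)
        rows.append(_snapshot(day, nh4, nox, ph, abund, labeled, oxidized))
    return pd.DataFrame(rows).set_index("day")


def _snapshot(day, nh4, nox, ph, abund, labeled, oxidized) -> dict:
    row = {"day": day, "nh4": nh4, "nox": nox, "ph": ph}
    for name, a in abund.items():
        row[f"abundance_{name}"] = a
        row[f"labeled_{name}"] = labeled[name]
        row[f"oxidized_{name}"] = oxidized[name]
    return row


def true_labeled_fraction(trajectory: pd.DataFrame, guild_name: str, day: int) -> float:
    """Fraction of a guild's copies carrying the 13C label at ``day``."""
    a = trajectory.loc[day, f"abundance_{guild_name}"]
    if a <= 0:
        return 0.0
    return float(trajectory.loc[day, f"labeled_{guild_name}"] / a)


# ---------------------------------------------------------------------------
# measurement noise


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with coefficient of
    variation ``cv`` (sigma^2 = ln(1 + cv^2), mu = -sigma^2/2)."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_measurements(
    trajectories: Mapping[tuple[str, str], pd.DataFrame], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy chemistry and abundance tables for every replicate microcosm.

    ``trajectories`` maps ``(soil_id, condition)`` to a frame from
    :func:`simulate_dynamics`.  Day 0 yields one triplicate set per soil x
    condition (isotope ``"none"``: sampled before CO2 amendment); later days
    yield independent triplicates per isotope.  Identical config (incl. seed)
    gives byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    chem_rows: list[dict] = []
    abund_rows: list[dict] = []
    for (soil, condition), traj in sorted(trajectories.items()):
        guild_names = [c.removeprefix("abundance_") for c in traj.columns if c.startswith("abundance_")]
        for day in config.sample_days:
            isotopes = ("none",) if day == 0 else ISOTOPES
            for iso in isotopes:
                for rep in range(1, config.replicates + 1):
                    mc = microcosm_id(soil, condition, iso, rep)
                    f = lognormal_factors(rng, config.chem_cv, 3)
                    chem_rows.append(
                        {
                            "soil": soil,
                            "condition": condition,
                            "isotope": iso,
                            "replicate": rep,
                            "microcosm_id": mc,
                            "day": day,
                            "nh4": traj.loc[day, "nh4"] * f[0],
                            "nox": traj.loc[day, "nox"] * f[1],
                            # pH is measured on the log scale already; additive
                            # noise scaled by chem_cv in pH units
                            "ph": traj.loc[day, "ph"] + (f[2] - 1.0) * 0.5,
                        }
                    )
                    g = lognormal_factors(rng, config.qpcr_cv, len(guild_names))
                    for k, name in enumerate(guild_names):
                        abund_rows.append(
                            {
                                "soil": soil,
                                "condition": condition,
                                "isotope": iso,
                                "replicate": rep,
                                "microcosm_id": mc,
                                "day": day,
                                "guild": name,
                                "copies": traj.loc[day, f"abundance_{name}"] * g[k],
                            }
                        )
    return pd.DataFrame(chem_rows), pd.DataFrame(abund_rows)


def microcosm_id(soil: str, condition: str, isotope: str, replicate: int) -> str:
    return f"{soil}-{condition}-{isotope}-r{replicate}"


# ---------------------------------------------------------------------------
# CsCl gradient


def gradient_bin_masses(center: float, config: SimConfig) -> np.ndarray:
    """Mass of a Gaussian DNA band (mean ``center``, sd ``density_sd``)
    in each fraction bin, renormalized to sum to 1 over the gradient."""
    from scipy.stats import norm

    edges = config.fraction_edges()  # descending
    cdf = norm.cdf(edges, loc=center, scale=config.density_sd)
    mass = cdf[:-1] - cdf[1:]  # descending edges: upper minus lower
    total = mass.sum()
    if total <= 0:
        raise ValueError("DNA band falls entirely outside the gradient range")
    return mass / total


def simulate_gradient(
    guild_abundance: float,
    labeled_fraction: float,
    guild: GuildParams,
    isotope: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-fraction amoA copies of one guild in one CsCl gradient.

    The unlabeled pool bands at ``bd_intercept + bd_gc_slope * GC``; under
    13C a ``labeled_fraction`` of the copies bands heavier by
    ``max_label_shift * atom_fraction_excess``.  Per-fraction copies are the
    total abundance split by the two bands' bin masses, then perturbed by
    qPCR noise (pass ``rng=None`` for noise-free output).

    Returns a frame with ``fraction_index`` (1 = heaviest), ``buoyant_density``
    and ``copies`` for all fractions.
    """
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ValueError(f"labeled_fraction must be in [0, 1], got {labeled_fraction}")
    if isotope not in ISOTOPES:
        raise ValueError(f"isotope must be one of {ISOTOPES}, got {isotope!r}")
    _require_nonneg("guild_abundance", guild_abundance)
    if isotope == "12C":
        labeled_fraction = 0.0
    center = config.bd_intercept + config.bd_gc_slope * guild.gc_content
    mass = (1.0 - labeled_fraction) * gradient_bin_masses(center, config)
    if labeled_fraction > 0:
        shifted = center + config.max_label_shift * config.atom_fraction_excess
        mass = mass + labeled_fraction * gradient_bin_masses(shifted, config)
    copies = guild_abundance * mass
    if rng is not None:
        copies = copies * lognormal_factors(rng, config.qpcr_cv, len(copies))
    return pd.DataFrame(
        {
            "fraction_index": np.arange(1, config.n_fractions + 1),
            "buoyant_density": config.fraction_densities(),
            "copies": copies,
        }
    )


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SyntheticDataset:
    """Three measurement tables plus the simulator's ground truth."""

    chemistry: pd.DataFrame
    abundance: pd.DataFrame
    gradient: pd.DataFrame
    truth: dict
    config: SimConfig


def generate_dataset(scenarios: Sequence[SoilScenario], config: SimConfig) -> SyntheticDataset:
    """Run the full design: every soil x condition trajectory, replicate
    measurements at each sampling day, and day-30 CsCl gradients for each
    isotope x replicate x guild (quantified fractions only in the table).

    The ground-truth record carries, per soil x condition x guild, the true
    net growth, labeled fraction and oxidized N, for recovery tests.
    """
    if len(scenarios) == 0:
        raise ValueError("at least one scenario is required")
    ids = [s.soil_id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate soil_id in scenarios: {ids}")

    final_day = max(config.sample_days)
    trajectories = {
        (s.soil_id, cond): simulate_dynamics(s, cond, config)
        for s in scenarios
        for cond in CONDITIONS
    }
    chemistry, abundance = simulate_measurements(trajectories, config)

    rng = np.random.default_rng((config.seed, 1))  # separate stream from measurements
    lo, hi = config.quantified_fractions
    grad_rows = []
    truth: dict = {"config": config.to_dict(), "soils": {}}
    for s in scenarios:
        truth["soils"][s.soil_id] = {}
        for cond in CONDITIONS:
            traj = trajectories[(s.soil_id, cond)]
            entry: dict = {
                "net_nox": float(traj.loc[final_day, "nox"] - traj.loc[0, "nox"]),
                "guilds": {},
            }
            for g in s.guilds:
                a0 = float(traj.loc[0, f"abundance_{g.guild_name}"])
                aT = float(traj.loc[final_day, f"abundance_{g.guild_name}"])
                lf = true_labeled_fraction(traj, g.guild_name, final_day)
                entry["guilds"][g.guild_name] = {
                    "initial_abundance": a0,
                    "final_abundance": aT,
                    "true_growth": aT - a0,
                    "labeled_fraction": lf,
                    "labeled_abundance": lf * aT,
                    "oxidized_ug_n": float(traj.loc[final_day, f"oxidized_{g.guild_name}"]),
                    "per_cell_activity": g.per_cell_activity,
                }
                for iso in ISOTOPES:
                    for rep in range(1, config.replicates + 1):
                        prof = simulate_gradient(
                            aT, lf if iso == "13C" else 0.0, g, iso, config, rng
                        )
                        prof = prof[(prof.fraction_index >= lo) & (prof.fraction_index <= hi)]
                        for _, row in prof.iterrows():
                            grad_rows.append(
                                {
                                    "soil": s.soil_id,
                                    "condition": cond,
                                    "isotope": iso,
                                    "replicate": rep,
                                    "microcosm_id": microcosm_id(s.soil_id, cond, iso, rep),
                                    "guild": g.guild_name,
                                    "fraction_index": int(row.fraction_index),
                                    "buoyant_density": row.buoyant_density,
                                    "copies": row.copies,
                                }
                            )
            truth["soils"][s.soil_id][cond] = entry
    return SyntheticDataset(chemistry, abundance, pd.DataFrame(grad_rows), truth, config)


# ---------------------------------------------------------------------------
# stock scenarios


def default_scenarios() -> list[SoilScenario]:
    """Five-soil land-use gradient: two forest soils (LF, E), a riparian
    soil (RR) and 2- and 7-year-old oil palm soils (OP2, OP7).

    The neutral soils (LF, E, RR) are acidified when "modified"; the acidic
    oil palm soils are limed.  Parameter magnitudes follow field-typical
    amoA abundances (1e4–1e8 copies g-1) with AOB favored at high pH, AOA
    tolerant of acidity, and comammox minor throughout.
    """

    def guilds(aoa0, aob0, com0, r_aoa, r_aob, r_com):
        return (
            GuildParams("AOA", aoa0, r_aoa[0], r_aoa[1], autotroph_fraction=0.8,
                        gc_content=0.45, per_cell_activity=2.6),
            GuildParams("AOB", aob0, r_aob[0], r_aob[1], autotroph_fraction=0.8,
                        gc_content=0.55, per_cell_activity=23.0),
            GuildParams("comammox", com0, r_com[0], r_com[1], autotroph_fraction=0.6,
                        gc_content=0.59, per_cell_activity=2.6),
        )

    return [
        # (growth d-1: native, modified); neutral soils: modified = acidified
        SoilScenario("LF", 6.8, 4.5, 2.5, 120.0, 45.0, 5.0,
                     guilds(4e5, 5e5, 8e4, (0.01, -0.02), (0.10, -0.05), (0.00, 0.00))),
        SoilScenario("E", 5.9, 4.5, 2.2, 110.0, 40.0, 6.0,
                     guilds(3e5, 4e5, 6e4, (0.02, -0.01), (0.11, -0.04), (0.00, -0.01))),
        SoilScenario("RR", 6.4, 4.5, 0.8, 130.0, 12.0, 4.0,
                     guilds(8e5, 1e5, 4e4, (0.10, 0.07), (0.08, -0.03), (0.00, -0.02))),
        # oil palm soils: modified = limed
        SoilScenario("OP2", 5.0, 6.5, 1.5, 90.0, 35.0, 8.0,
                     guilds(8e4, 6e4, 2e5, (0.00, 0.02), (0.02, 0.11), (0.07, 0.08))),
        SoilScenario("OP7", 5.0, 6.5, 2.0, 100.0, 50.0, 10.0,
                     guilds(1.5e6, 2e4, 1e5, (0.08, 0.12), (0.03, 0.10), (0.00, 0.01))),
    ]


def closure_scenarios() -> list[SoilScenario]:
    """Scenario set for end-to-end conservation checks: every guild grows
    (rate >= 0.1 d-1), is fully autotrophic, and ammonium never limits, so
    the summed guild contributions at the true per-cell activity bound the
    measured NOx production from above in every soil."""
    out = []
    for s in default_scenarios():
        guilds = tuple(
            replace(
                g,
                growth_rate_native=max(0.1, g.growth_rate_native),
                growth_rate_modified=max(0.1, g.growth_rate_modified),
                autotroph_fraction=1.0,
            )
            for g in s.guilds
        )
        out.append(replace(s, guilds=guilds, mineralization_rate=200.0, initial_nh4=500.0))
    return out
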