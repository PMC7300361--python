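"""Apportioning measured nitrification to ammonia-oxidizer guilds.

Each guild's putative NOx- production is its growing-cell count times the
highest maximum specific cell activity recorded for a cultured
representative, held for the whole incubation — deliberately an upper
bound.  Whatever measured NOx- production the summed guild estimates do
not cover is reported as "unaccounted"; if they exceed it, the breakdown
is flagged overexplained and the estimates are reported as-is, never
rescaled.

Default cell activities (fmol NH3 cell-1 h-1): AOA 2.6 (Nitrososphaera
viennensis), AOB 23 (Nitrosospira multiformis), comammox 2.6 (Nitrospira
inopinata, derived from Vmax via biomass conversion factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .stats import GrowthEstimate
from .synthetic import UG_N_PER_FMOL_NH3

#: highest recorded maximum specific cell activities, fmol NH3 cell-1 h-1
DEFAULT_ACTIVITIES = {"AOA": 2.6, "AOB": 23.0, "comammox": 2.6}

#: kinetic inputs behind the comammox constant: Vmax 14.8 µmol NH3 mg-1
#: protein h-1, 5.7 g wet weight per g protein, 1e12 cells per g wet weight
COMAMMOX_DERIVATION = (14.8, 5.7, 1e12)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class CellActivity:
    guild: str
    activity: float  # fmol NH3 cell-1 h-1
    provenance: str = "default"

    def __post_init__(self) -> None:
        if not self.activity > 0:
            raise ValueError(f"activity must be > 0, got {self.activity}")

    @property
    def presented(self) -> float:
        return round_sig(self.activity, 2)


@dataclass(frozen=True)
class ActivityDerivationInput:
    """Culture kinetics from which a per-cell activity is derived."""

    vmax: float  # µmol NH3 mg-1 protein h-1
    wet_weight_per_protein: float  # g wet weight g-1 protein
    cells_per_g_wet: float  # cells g-1 wet weight

    def __post_init__(self) -> None:
        for name in ("vmax", "wet_weight_per_protein", "cells_per_g_wet"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


def derive_cell_activity(
    inputs: ActivityDerivationInput, guild: str = "comammox", provenance: str = "derived"
) -> CellActivity:
    """Per-cell activity from Vmax and biomass conversion factors.

    fmol cell-1 h-1 = Vmax [µmol mg-1 protein h-1] x 1e3 [mg -> g protein]
    / wet_weight_per_protein [g wet g-1 protein] / cells_per_g_wet
    x 1e9 [µmol -> fmol].  No rounding is applied here; use
    :attr:`CellActivity.presented` for the 2-significant-figure display.
    """
    per_g_protein = inputs.vmax * 1e3  # µmol g-1 protein h-1
    per_g_wet = per_g_protein / inputs.wet_weight_per_protein
    per_cell_umol = per_g_wet / inputs.cells_per_g_wet
    return CellActivity(guild, per_cell_umol * 1e9, provenance)


def guild_contribution(
    growth: GrowthEstimate | float,
    activity: CellActivity | float,
    hours: float = 720.0,
    copies_per_cell: float = 1.0,
) -> float:
    """Putative NOx- production (µg N g-1 dry soil) of one guild.

    The growing population (amoA copies divided by copies per cell) is held
    at ``activity`` for ``hours``; undetected or negative growth contributes
    zero.  1 fmol NH3 carries 1.4e-8 µg N.
    """
    if hours <= 0:
        raise ValueError(f"hours must be > 0, got {hours}")
    if copies_per_cell < 1:
        raise ValueError(f"copies_per_cell must be >= 1, got {copies_per_cell}")
    if isinstance(growth, GrowthEstimate):
        g = growth.value if growth.detected else 0.0
    else:
        g = float(growth)
    g = max(0.0, g)
    act = activity.activity if isinstance(activity, CellActivity) else float(activity)
    if act <= 0:
        raise ValueError(f"activity must be > 0, got {act}")
    cells = g / copies_per_cell
    return cells * act * hours * UG_N_PER_FMOL_NH3


@dataclass(frozen=True)
class ContributionBreakdown:
    """Per-guild putative NOx- production vs the measured total.

    When not overexplained, contributions + unaccounted = measured exactly.
    """

    soil_id: str
    condition: str
    contributions: Mapping[str, float]  # µg N g-1 dry soil
    measured_nox: float
    unaccounted: float
    overexplained: bool
    growth_method: str = "sip"

    def __post_init__(self) -> None:
        object.__setattr__(self, "contributions", dict(self.contributions))
        if any(v < 0 for v in self.contributions.values()):
            raise ValueError("contributions must be >= 0")
        if self.unaccounted < 0:
            raise ValueError("unaccounted must be >= 0")

    @property
    def total_explained(self) -> float:
        return sum(self.contributions.values())

    @property
    def unaccounted_fraction(self) -> float:
        return self.unaccounted / self.measured_nox if self.measured_nox > 0 else 0.0


def apportion(
    measured_nox: float,
    contributions: Mapping[str, float],
    soil_id: str = "",
    condition: str = "",
    growth_method: str = "sip",
) -> ContributionBreakdown:
    """Split measured NOx- production into guild contributions + residual.

    ``unaccounted = max(0, measured - sum(contributions))``; if the summed
    upper-bound estimates exceed the measurement the breakdown is flagged
    ``overexplained`` and left unrescaled.
    """
    if measured_nox < 0:
        raise ValueError(f"measured_nox must be >= 0, got {measured_nox}")
    for guild, v in contributions.items():
        if v < 0:
            raise ValueError(f"negative contribution for {guild}: {v}")
    total = sum(contributions.values())
    over = total > measured_nox
    unaccounted = max(0.0, measured_nox - total)
    return ContributionBreakdown(
        soil_id, condition, dict(contributions), measured_nox, unaccounted, over, growth_method
    )


def scale_area_emission(per_area_rate: float, area_ha: float) -> float:
    """Scale a per-area N flux (kg N ha-1 yr-1) to a total in Tg N yr-1.

    Presentation rounding (2 decimals) is left to the caller; e.g. a field
    rate of 1.2 kg N ha-1 yr-1 over 1.9e7 ha gives 0.0228 Tg N yr-1.
    """
    if per_area_rate < 0 or area_ha < 0:
        raise ValueError("per_area_rate and area must be >= 0")
    return per_area_rate * area_ha * 1e-9
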