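"""End-to-end analysis: rates -> growth -> SIP labeling -> stability ->
apportionment, over every soil x pH condition of a dataset.

The stage order follows the experiment's logic: chemistry gives net
nitrification; qPCR abundance gives temporal growth and the stability
index; the CsCl gradients identify and quantify the 13C-labeled (growing,
autotrophic) populations; and growing-population counts times cell-specific
activities apportion the measured NOx- production among guilds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .apportion import apportion, guild_contribution
from .io import Dataset, RunConfig
from .sip import LabelingCall, detect_labeling, labeled_abundance, labeled_proportion, normalize_profile
from .stats import (
    ChemMeasurement,
    GrowthEstimate,
    SummaryStats,
    growth_by_qpcr,
    net_nox_production,
    stability_index,
)
from .synthetic import GUILDS

log = logging.getLogger("nitrosip")


@dataclass
class ResultBundle:
    """All result tables of one pipeline run, plus a JSON-able summary."""

    rates: pd.DataFrame
    growth: pd.DataFrame
    labeling: pd.DataFrame
    stability: pd.DataFrame
    contributions: pd.DataFrame
    summary: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("rates", "growth", "labeling", "stability", "contributions"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        p = outdir / "summary.json"
        p.write_text(json.dumps(self.summary, indent=2, sort_keys=True, default=float))
        paths["summary"] = p
        return paths


def _chem_measurements(df: pd.DataFrame, soil: str, condition: str, day: int) -> list[ChemMeasurement]:
    sub = df[(df.soil == soil) & (df.condition == condition) & (df.day == day)]
    return [
        ChemMeasurement(soil, condition, int(r.replicate), int(r.day), r.nh4, r.nox, r.ph)
        for r in sub.itertuples()
    ]


def _profiles(gradient: pd.DataFrame, soil: str, condition: str, guild: str, isotope: str):
    sub = gradient[
        (gradient.soil == soil)
        & (gradient.condition == condition)
        & (gradient.guild == guild)
        & (gradient.isotope == isotope)
    ]
    out = []
    for _, grp in sub.groupby("replicate"):
        lo, hi = int(grp.fraction_index.min()), int(grp.fraction_index.max())
        out.append(normalize_profile(grp, quantified_range=(lo, hi), guild=guild))
    return out


def run_pipeline(dataset: Dataset, config: RunConfig | None = None) -> ResultBundle:
    """Run every analysis stage on a validated dataset.

    Deterministic given the dataset and config; each stage failure is
    re-raised with the stage name and the soil/condition/guild it hit.
    """
    config = config or RunConfig()
    days = dataset.days
    final_day = config.final_day if config.final_day is not None else max(days)
    hours = config.hours if config.hours else final_day * 24.0
    activities = config.activity_map()

    rates_rows, growth_rows, label_rows, stab_rows, contrib_rows = [], [], [], [], []
    summary: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "final_day": final_day,
        "soils": {},
    }
    stage = "start"
    for soil in dataset.soils:
        summary["soils"][soil] = {}
        for condition in ("native", "modified"):
            try:
                entry = _analyze_cell(
                    dataset, soil, condition, final_day, hours, activities, config,
                    rates_rows, growth_rows, label_rows, contrib_rows,
                )
            except Exception as exc:  # annotate with the failing keys
                raise RuntimeError(f"pipeline failed at {soil}/{condition}: {exc}") from exc
            summary["soils"][soil][condition] = entry
        # stability: modified vs native day-30 abundance per guild
        stage = "stability"
        try:
            stab_entry = {}
            for guild in GUILDS:
                m = _day_abundances(dataset.abundance, soil, "modified", guild, final_day)
                n = _day_abundances(dataset.abundance, soil, "native", guild, final_day)
                if len(m) == 0 or len(n) == 0 or np.mean(n) <= 0:
                    continue
                idx = stability_index(m, n, guild=guild)
                stab_rows.append(
                    {
                        "soil": soil,
                        "guild": guild,
                        "stability_pct": idx.value,
                        "compensation": idx.compensation,
                        "per_replicate": ";".join(f"{v:.4f}" for v in idx.per_replicate),
                    }
                )
                stab_entry[guild] = {"stability_pct": idx.value, "compensation": idx.compensation}
            summary["soils"][soil]["stability"] = stab_entry
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage {stage} for {soil}: {exc}") from exc

    bundle = ResultBundle(
        pd.DataFrame(rates_rows),
        pd.DataFrame(growth_rows),
        pd.DataFrame(label_rows),
        pd.DataFrame(stab_rows),
        pd.DataFrame(contrib_rows),
        summary,
    )
    log.info(
        "pipeline complete: %d soils, %d rate rows, seed=%s, version=%s",
        len(dataset.soils), len(rates_rows), config.seed, __version__,
    )
    return bundle


def _day_abundances(abund: pd.DataFrame, soil, condition, guild, day) -> np.ndarray:
    sub = abund[
        (abund.soil == soil) & (abund.condition == condition)
        & (abund.guild == guild) & (abund.day == day)
    ]
    return sub.copies.to_numpy(dtype=float)


def _analyze_cell(
    dataset, soil, condition, final_day, hours, activities, config,
    rates_rows, growth_rows, label_rows, contrib_rows,
):
    """All per-(soil, condition) stages; appends rows, returns summary dict."""
    # --- net nitrification ---------------------------------------------
    d0 = _chem_measurements(dataset.chemistry, soil, condition, 0)
    dT = _chem_measurements(dataset.chemistry, soil, condition, final_day)
    rate = net_nox_production(d0, dT)
    rates_rows.append(
        {
            "soil": soil,
            "condition": condition,
            "delta_nox": rate.delta.mean,
            "se": rate.delta.se,
            "days": rate.days,
            "t": rate.test.t,
            "p": rate.test.p,
            "significant": rate.test.significant(config.alpha),
        }
    )
    entry = {"net_nox": rate.delta.mean, "net_nox_p": rate.test.p}

    # --- per-guild growth, labeling, contributions ----------------------
    contributions = {}
    entry["guilds"] = {}
    for guild in GUILDS:
        a0 = _day_abundances(dataset.abundance, soil, condition, guild, 0)
        aT = _day_abundances(dataset.abundance, soil, condition, guild, final_day)
        if len(a0) == 0 or len(aT) == 0:
            continue
        g_qpcr = growth_by_qpcr(
            SummaryStats.from_sample(a0), SummaryStats.from_sample(aT),
            alpha=config.alpha, guild=guild,
        )
        # SIP: labeling call + heavy-fraction quantification
        p12 = _profiles(dataset.gradient, soil, condition, guild, "12C")
        p13 = _profiles(dataset.gradient, soil, condition, guild, "13C")
        call = detect_labeling(
            p12, p13, delta_min=config.delta_min, alpha=config.alpha, guild=guild
        )
        g_sip = GrowthEstimate(guild, "sip", 0.0, 0.0, False)
        labeled_pct = float("nan")
        total_13c = float(np.mean(aT)) if len(aT) else 0.0
        if call.labeled:
            mean, se, _ = labeled_abundance(
                p13, total_13c, heavy_threshold=config.heavy_threshold,
                profiles_12c=p12, subtract_12c=config.subtract_12c,
            )
            g_sip = GrowthEstimate(guild, "sip", mean, se, True, call.p_value)
            labeled_pct = labeled_proportion(mean, total_13c) if total_13c > 0 else float("nan")
        for g in (g_qpcr, g_sip):
            growth_rows.append(
                {
                    "soil": soil,
                    "condition": condition,
                    "guild": guild,
                    "method": g.method,
                    "growth": g.value,
                    "se": g.se,
                    "detected": g.detected,
                    "display": g.formatted(),
                }
            )
        label_rows.append(
            {
                "soil": soil,
                "condition": condition,
                "guild": guild,
                "labeled": call.labeled,
                "delta_wmd": call.delta_wmd,
                "p": call.p_value,
                "labeled_abundance": g_sip.value if g_sip.detected else float("nan"),
                "labeled_pct": labeled_pct,
            }
        )
        chosen = g_sip if config.growth_method == "sip" else g_qpcr
        contributions[guild] = guild_contribution(
            chosen, activities.get(guild, 2.6), hours=hours,
            copies_per_cell=config.copies_per_cell,
        )
        entry["guilds"][guild] = {
            "growth_qpcr": g_qpcr.value,
            "growth_qpcr_detected": g_qpcr.detected,
            "growth_sip": g_sip.value if g_sip.detected else None,
            "labeled": call.labeled,
            "labeled_pct": None if np.isnan(labeled_pct) else labeled_pct,
        }

    # --- apportionment ---------------------------------------------------
    breakdown = apportion(
        max(0.0, rate.delta.mean), contributions, soil_id=soil, condition=condition,
        growth_method=config.growth_method,
    )
    row = {"soil": soil, "condition": condition, "measured_nox": breakdown.measured_nox}
    for guild in GUILDS:
        row[f"contribution_{guild}"] = breakdown.contributions.get(guild, 0.0)
    row["unaccounted"] = breakdown.unaccounted
    row["overexplained"] = breakdown.overexplained
    contrib_rows.append(row)
    entry["apportionment"] = {
        "contributions": breakdown.contributions,
        "unaccounted": breakdown.unaccounted,
        "overexplained": breakdown.overexplained,
    }
    return entry
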