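"""Nitrification rates, qPCR growth, stability indices, and classical tests.

The experimental questions are answered with the standard small-sample
toolkit: net nitrification as the 30-day increase in NOx- tested against no
change, guild growth as the day-30 minus day-0 qPCR abundance with a
one-sided two-sample t test, a proportional stability index
``100 x (M - N) / N`` comparing pH-modified (M) to native (N) abundance,
and fixed-effects ANOVA with Tukey HSD letters for the factorial design.

Two-sample t statistics are reconstructed from summary statistics
(mean, SE, n), which is exact: when the summaries come from the raw
replicates the result equals the full-data test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ChemMeasurement:
    """One microcosm's chemistry at one sampling day."""

    soil_id: str
    condition: str
    replicate: int
    day: int
    nh4: float  # µg N g-1 dry soil
    nox: float  # µg N g-1 dry soil
    ph: float

    def __post_init__(self) -> None:
        if self.nh4 < 0 or self.nox < 0:
            raise ValueError(
                f"negative concentration in {self.soil_id}/{self.condition} "
                f"rep {self.replicate} day {self.day}"
            )


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard error of the mean, and sample size."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError(f"se must be >= 0, got {self.se}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @classmethod
    def from_sample(cls, values: Sequence[float]) -> "SummaryStats":
        x = np.asarray(values, dtype=float)
        se = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
        return cls(float(x.mean()), se, len(x))

    @property
    def sd(self) -> float:
        return self.se * math.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float  # two-sided unless stated otherwise by the caller

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


@dataclass(frozen=True)
class GrowthEstimate:
    """A guild's growing-population abundance by one estimator.

    ``method="qpcr"``: day-30 minus day-0 abundance (may be negative);
    ``method="sip"``: 13C-labeled copies in the heavy fractions.
    ``detected`` requires a significant *increase*; undetected growth is
    reported as "n.d." in formatted output.
    """

    guild: str
    method: str  # "qpcr" | "sip"
    value: float  # Δ amoA copies g-1 dry soil
    se: float
    detected: bool
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.method not in ("qpcr", "sip"):
            raise ValueError(f"method must be 'qpcr' or 'sip', got {self.method!r}")

    def formatted(self) -> str:
        if not self.detected:
            return "n.d."
        return f"{self.value:.2g} ± {self.se:.2g}"


@dataclass(frozen=True)
class StabilityIndex:
    """Proportional abundance change under pH modification vs native pH.

    Zero is the neutral point (perfect stability); negative values indicate
    undercompensation, positive overcompensation.  Bounded below by -100 for
    nonnegative abundances, unbounded above.
    """

    guild: str
    value: float  # percent
    per_replicate: tuple[float, ...]
    compensation: str = field(init=False)

    def __post_init__(self) -> None:
        comp = "neutral" if self.value == 0 else ("under" if self.value < 0 else "over")
        object.__setattr__(self, "compensation", comp)
        object.__setattr__(self, "per_replicate", tuple(self.per_replicate))


# ---------------------------------------------------------------------------
# two-sample machinery


def summary_ttest(a: SummaryStats, b: SummaryStats, variant: str = "pooled") -> TTestResult:
    """Two-sample t test reconstructed from (mean, SE, n) summaries.

    ``pooled`` is the classical Student test (df = n_a + n_b - 2);
    ``welch`` uses the Welch-Satterthwaite df.  Returns the two-sided p.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("inference needs n >= 2 in both groups")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    va, vb = a.sd**2, b.sd**2
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        denom = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        ea, eb = va / a.n, vb / b.n
        denom = math.sqrt(ea + eb)
        df = (ea + eb) ** 2 / (ea**2 / (a.n - 1) + eb**2 / (b.n - 1)) if ea + eb > 0 else a.n + b.n - 2
    if denom == 0:
        t = 0.0 if a.mean == b.mean else math.copysign(math.inf, a.mean - b.mean)
    else:
        t = (a.mean - b.mean) / denom
    p = 2 * sps.t.sf(abs(t), df) if math.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return TTestResult(float(t), float(df), float(p))


# ---------------------------------------------------------------------------
# rates and growth


@dataclass(frozen=True)
class NetRateResult:
    """Net NOx- production over an incubation with its test against no change."""

    soil_id: str
    condition: str
    delta: SummaryStats  # µg N g-1 dry soil over the interval
    test: TTestResult
    days: int

    @property
    def rate_per_day(self) -> float:
        return self.delta.mean / self.days if self.days else float("nan")


def net_nox_production(
    day0: Sequence[ChemMeasurement], dayT: Sequence[ChemMeasurement]
) -> NetRateResult:
    """Increase in NOx- between day 0 and the final day, tested vs no change.

    The point estimate is the difference of replicate means; its SE is
    propagated as sqrt(se0^2 + seT^2) and the null of no change is assessed
    with a Student's t test on the two replicate sets.
    """
    d0, dT = list(day0), list(dayT)
    if len(d0) < 2 or len(dT) < 2:
        raise ValueError("need >= 2 replicates at each day")
    keys = {(m.soil_id, m.condition) for m in d0} | {(m.soil_id, m.condition) for m in dT}
    if len(keys) != 1:
        raise ValueError(f"mismatched soil/condition across replicates: {sorted(keys)}")
    soil, condition = keys.pop()
    s0 = SummaryStats.from_sample([m.nox for m in d0])
    sT = SummaryStats.from_sample([m.nox for m in dT])
    delta = SummaryStats(sT.mean - s0.mean, math.sqrt(s0.se**2 + sT.se**2), min(s0.n, sT.n))
    test = summary_ttest(sT, s0, variant="pooled")
    days = max(m.day for m in dT) - max(m.day for m in d0)
    return NetRateResult(soil, condition, delta, test, days)


def growth_by_qpcr(
    day0: SummaryStats, day30: SummaryStats, alpha: float = 0.05, guild: str = ""
) -> GrowthEstimate:
    """Guild growth as final minus initial qPCR abundance.

    Growth is *detected* only for a significant increase (one-sided
    two-sample t from the summaries, p < alpha, df = n0 + n30 - 2); a
    decline or a nonsignificant difference is reported undetected ("n.d."),
    with the signed point estimate still carried.
    """
    value = day30.mean - day0.mean
    se = math.sqrt(day0.se**2 + day30.se**2)
    if day0.n < 2 or day30.n < 2:
        return GrowthEstimate(guild, "qpcr", value, se, False)
    res = summary_ttest(day30, day0, variant="pooled")
    p_one = res.p / 2 if res.t > 0 else 1 - res.p / 2
    detected = value > 0 and p_one < alpha
    return GrowthEstimate(guild, "qpcr", value, se, detected, float(p_one))


# ---------------------------------------------------------------------------
# stability


def stability_index(
    modified: Sequence[float], native: Sequence[float], guild: str = ""
) -> StabilityIndex:
    """Stability = 100 x (M - N) / N with M, N the day-30 mean abundances
    in pH-modified and native soil.

    Per-replicate indices place each modified replicate against the native
    mean (microcosms are independent, so replicate pairing across conditions
    is arbitrary); their mean equals the headline value.
    """
    m = np.asarray(modified, dtype=float)
    n = np.asarray(native, dtype=float)
    if np.any(m < 0) or np.any(n < 0):
        raise ValueError("abundances must be >= 0")
    n_mean = n.mean()
    if n_mean <= 0:
        raise ValueError("native mean abundance must be > 0 for a stability index")
    per_rep = tuple(100.0 * (mi - n_mean) / n_mean for mi in m)
    value = 100.0 * (m.mean() - n_mean) / n_mean
    return StabilityIndex(guild, float(value), per_rep)


def compare_stability(
    index_a: StabilityIndex, index_b: StabilityIndex, variant: str = "pooled"
) -> TTestResult:
    """Independent two-sample t test on per-replicate stability indices."""
    a, b = index_a.per_replicate, index_b.per_replicate
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 per-replicate indices on both sides")
    return summary_ttest(SummaryStats.from_sample(a), SummaryStats.from_sample(b), variant)


# ---------------------------------------------------------------------------
# ANOVA + Tukey


@dataclass
class AnovaResult:
    table: pd.DataFrame  # classical ANOVA table (sum_sq, df, F, PR(>F))
    tukey: pd.DataFrame | None  # pairwise comparisons between cell groups
    letters: dict[str, str] | None  # compact letter display per group


def anova_with_posthoc(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    alpha: float = 0.05,
    interaction: bool = True,
) -> AnovaResult:
    """Fixed-effects ANOVA over one or two factors with Tukey HSD letters.

    One factor gives the one-way decomposition (e.g. effect of incubation
    time); two factors give the two-way table, with interaction by default.
    Tukey's HSD runs on the factor-combination cells and the grouping
    letters summarize it as displayed above bar charts: groups sharing a
    letter are not significantly different.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("factors must name one or two columns")
    df = data[[response] + factors].dropna().copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    df = df.rename(columns={response: "_y"})
    terms = [f"C({f})" for f in factors]
    rhs = " * ".join(terms) if (len(terms) == 2 and interaction) else " + ".join(terms)
    model = ols(f"_y ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    group = df[factors[0]].astype(str)
    for f in factors[1:]:
        group = group + ":" + df[f].astype(str)
    tukey_df = None
    letters = None
    if group.nunique() >= 2 and group.value_counts().min() >= 2:
        res = pairwise_tukeyhsd(df["_y"].to_numpy(), group.to_numpy(), alpha=alpha)
        tukey_df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        means = df.groupby(group)["_y"].mean().sort_values(ascending=False)
        nonsig = {
            frozenset((row["group1"], row["group2"]))
            for _, row in tukey_df.iterrows()
            if not row["reject"]
        }
        letters = _compact_letters(list(means.index), nonsig)
    return AnovaResult(table, tukey_df, letters)


def _compact_letters(groups: list[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups ordered by descending mean; two groups share a letter iff their
    pairwise comparison is not significant.
    """
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) in nonsig for other in s):
                s.add(g)
                placed = True
        if not placed:
            # need a new letter set containing g plus every earlier group
            # it is compatible with
            new = {g} | {
                other
                for other in groups
                if other != g and frozenset((g, other)) in nonsig
            }
            # keep only mutually compatible members (greedy, ordered)
            kept: set[str] = {g}
            for other in groups:
                if other in new and other != g:
                    if all(frozenset((other, k)) in nonsig for k in kept):
                        kept.add(other)
            letter_sets.append(kept)
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p values (optional; no correction is applied by default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
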