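"""CsCl buoyant-density gradient analysis for DNA stable-isotope probing.

A growing, autotrophic population incubated under 13C-CO2 incorporates the
heavy isotope into newly synthesized DNA, which therefore bands at a higher
buoyant density in a CsCl gradient than unlabeled DNA.  This module turns
raw per-fraction qPCR counts into normalized density profiles, decides
whether a guild is 13C-labeled (by comparing 12C and 13C profiles across
replicate microcosms), and quantifies the labeled — i.e. actively growing —
population from the heavy-fraction mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: default minimum 13C-12C weighted-mean-density shift called as labeling (g ml-1)
DEFAULT_DELTA_MIN = 0.005
#: default buoyant density at and above which a fraction counts as "heavy" (g ml-1)
DEFAULT_HEAVY_THRESHOLD = 1.725

_PROFILE_TOL = 1e-9


@dataclass(frozen=True)
class GradientFraction:
    """One quantified fraction of one CsCl gradient."""

    microcosm_id: str
    isotope: str
    fraction_index: int
    buoyant_density: float  # g ml-1
    copies: float  # amoA copies (any consistent per-gradient scale)

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError(f"copies must be >= 0, got {self.copies}")
        if self.buoyant_density <= 0:
            raise ValueError(f"buoyant_density must be > 0, got {self.buoyant_density}")


@dataclass(frozen=True)
class DensityProfile:
    """Normalized buoyant-density distribution of one guild in one gradient.

    ``relative_abundance`` is each fraction's share of the total copies over
    the quantified fractions; it sums to 1 within 1e-9 (asserted on
    construction).  Densities are stored heaviest-first.
    """

    microcosm_id: str
    isotope: str
    guild: str
    densities: tuple[float, ...]
    relative_abundance: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        w = np.asarray(self.relative_abundance, dtype=float)
        if d.shape != w.shape or d.size < 3:
            raise ValueError("profile needs >= 3 (density, abundance) pairs of equal length")
        if np.any(w < 0):
            raise ValueError("relative abundances must be >= 0")
        if abs(w.sum() - 1.0) > _PROFILE_TOL:
            raise ValueError(f"relative abundances must sum to 1 +/- {_PROFILE_TOL}, got {w.sum()}")
        if np.any(np.diff(d) >= 0):
            raise ValueError("densities must be strictly decreasing with fraction order")
        object.__setattr__(self, "densities", tuple(d))
        object.__setattr__(self, "relative_abundance", tuple(w))

    def heavy_mass(self, threshold: float) -> float:
        """Total relative abundance at buoyant density >= ``threshold``."""
        d = np.asarray(self.densities)
        if threshold > d.max() or threshold < d.min():
            raise ValueError(
                f"heavy threshold {threshold} outside observed density range "
                f"[{d.min():.4f}, {d.max():.4f}]"
            )
        return float(np.asarray(self.relative_abundance)[d >= threshold].sum())


@dataclass(frozen=True)
class LabelingCall:
    """Outcome of the 12C-vs-13C labeling decision for one guild.

    ``labeled`` is None for a no-call (no usable signal on one side),
    distinct from an explicit "unlabeled".  ``delta_wmd`` is the mean 13C
    minus 12C abundance-weighted density shift over replicates.
    """

    guild: str
    labeled: bool | None
    delta_wmd: float
    p_value: float
    n_12c: int
    n_13c: int
    heavy_threshold: float = DEFAULT_HEAVY_THRESHOLD
    labeled_abundance: float | None = None
    labeled_se: float | None = None

    @property
    def no_call(self) -> bool:
        return self.labeled is None


def normalize_profile(
    fractions: Sequence[GradientFraction] | pd.DataFrame,
    quantified_range: tuple[int, int] = (2, 14),
    guild: str = "",
) -> DensityProfile | None:
    """Normalize per-fraction counts to a proportion of the whole gradient.

    Accepts either a sequence of :class:`GradientFraction` or a frame with
    ``fraction_index``, ``buoyant_density``, ``copies`` (plus optionally
    ``microcosm_id``/``isotope``/``guild``) for one gradient.  Fractions
    outside ``quantified_range`` are dropped.  Returns None — an explicit
    no-signal outcome — when every quantified fraction has zero copies.
    """
    if isinstance(fractions, pd.DataFrame):
        df = fractions.copy()
        meta = {
            "microcosm_id": str(df["microcosm_id"].iloc[0]) if "microcosm_id" in df else "",
            "isotope": str(df["isotope"].iloc[0]) if "isotope" in df else "",
            "guild": str(df["guild"].iloc[0]) if "guild" in df else guild,
        }
    else:
        fr = list(fractions)
        df = pd.DataFrame(
            {
                "fraction_index": [f.fraction_index for f in fr],
                "buoyant_density": [f.buoyant_density for f in fr],
                "copies": [f.copies for f in fr],
            }
        )
        meta = {
            "microcosm_id": fr[0].microcosm_id if fr else "",
            "isotope": fr[0].isotope if fr else "",
            "guild": guild,
        }
    lo, hi = quantified_range
    df = df[(df.fraction_index >= lo) & (df.fraction_index <= hi)]
    df = df.sort_values("fraction_index")
    if len(df) < 3:
        raise ValueError(f"need >= 3 quantified fractions, got {len(df)}")
    if (df.copies < 0).any():
        bad = df[df.copies < 0].fraction_index.tolist()
        raise ValueError(f"negative copies in fractions {bad}")
    total = df.copies.sum()
    if total <= 0:
        return None  # no signal anywhere in the gradient
    return DensityProfile(
        meta["microcosm_id"],
        meta["isotope"],
        meta["guild"],
        tuple(df.buoyant_density),
        tuple(df.copies / total),
    )


def weighted_mean_density(profile: DensityProfile) -> float:
    """Abundance-weighted mean buoyant density (g ml-1) of a profile.

    This is the scalar used to compare 12C and 13C band positions: isotope
    incorporation moves it heavier.
    """
    d = np.asarray(profile.densities)
    w = np.asarray(profile.relative_abundance)
    if abs(w.sum() - 1.0) > _PROFILE_TOL:  # defensive; guaranteed by construction
        raise ValueError("profile is not normalized")
    return float(np.dot(d, w))


def detect_labeling(
    profiles_12c: Iterable[DensityProfile | None],
    profiles_13c: Iterable[DensityProfile | None],
    delta_min: float = DEFAULT_DELTA_MIN,
    alpha: float = 0.05,
    guild: str | None = None,
) -> LabelingCall:
    """Decide whether a guild's DNA is 13C-labeled.

    Labeling is called when the 13C replicate profiles band at a distinctly
    higher density than the 12C profiles: the mean weighted-mean-density
    shift must reach ``delta_min`` AND a one-sided two-sample t test on the
    replicate weighted mean densities must give p < ``alpha``.  Profiles that
    are None (no signal) are dropped; if either isotope has none left the
    outcome is a no-call (``labeled=None``), distinct from "unlabeled".
    """
    p12 = [p for p in profiles_12c if p is not None]
    p13 = [p for p in profiles_13c if p is not None]
    if guild is None:
        guild = p13[0].guild if p13 else (p12[0].guild if p12 else "")
    for plist in (p12, p13):
        for p in plist:
            if p.guild != guild:
                raise ValueError(f"mixed guilds in labeling call: {p.guild!r} vs {guild!r}")
    if not p12 or not p13:
        return LabelingCall(guild, None, float("nan"), float("nan"), len(p12), len(p13))
    w12 = np.array([weighted_mean_density(p) for p in p12])
    w13 = np.array([weighted_mean_density(p) for p in p13])
    delta = float(w13.mean() - w12.mean())
    if len(w12) >= 2 and len(w13) >= 2:
        with warnings.catch_warnings():
            # zero within-group variance (e.g. noise-free input) gives a nan
            # statistic; the effect-size criterion then decides alone
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p_two = sps.ttest_ind(w13, w12, equal_var=True)
        p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    else:  # single replicate on a side: effect-size criterion only
        p_one = float("nan")
    labeled = delta >= delta_min and (np.isnan(p_one) or p_one < alpha)
    return LabelingCall(guild, bool(labeled), delta, float(p_one), len(w12), len(w13))


def labeled_abundance(
    profiles_13c: Iterable[DensityProfile | None],
    total_abundance: float,
    heavy_threshold: float = DEFAULT_HEAVY_THRESHOLD,
    profiles_12c: Iterable[DensityProfile | None] | None = None,
    subtract_12c: bool = False,
) -> tuple[float, float, list[float]]:
    """Copies g-1 of the 13C-labeled (growing) population.

    Each 13C replicate contributes ``total_abundance`` x its relative
    abundance at buoyant density >= ``heavy_threshold``; the estimate is the
    replicate mean with its standard error.  With ``subtract_12c`` the mean
    12C heavy-window proportion is subtracted first (default off: the plain
    heavy-fraction count), clipping at zero.

    Returns ``(mean, se, per_replicate)``.
    """
    if total_abundance < 0:
        raise ValueError(f"total_abundance must be >= 0, got {total_abundance}")
    p13 = [p for p in profiles_13c if p is not None]
    if not p13:
        raise ValueError("no 13C profiles with signal; make a labeling call first")
    background = 0.0
    if subtract_12c:
        if profiles_12c is None:
            raise ValueError("subtract_12c requires 12C profiles")
        p12 = [p for p in profiles_12c if p is not None]
        if p12:
            background = float(np.mean([p.heavy_mass(heavy_threshold) for p in p12]))
    per_rep = [
        max(0.0, (p.heavy_mass(heavy_threshold) - background)) * total_abundance for p in p13
    ]
    mean = float(np.mean(per_rep))
    se = float(np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))) if len(per_rep) > 1 else 0.0
    return mean, se, per_rep


def labeled_proportion(labeled: float, total: float) -> float:
    """Labeled population as a percentage of the total, clipped to [0, 100]."""
    if total <= 0:
        raise ValueError(f"total abundance must be > 0, got {total}")
    if labeled < 0:
        raise ValueError(f"labeled abundance must be >= 0, got {labeled}")
    raw = 100.0 * labeled / total
    if raw > 100.0:
        warnings.warn(
            f"labeled abundance exceeds total ({raw:.1f}%); clipping to 100%", stacklevel=2
        )
        return 100.0
    return raw
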