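"""Per-group dispersion statistics for trap counts.

For each group of sampling units (sticky traps within a site on one date, for
one instar) the module computes the mean density x-bar, sample variance s^2,
Lloyd's mean crowding m* = x-bar + (s^2/x-bar - 1), the index of dispersion
I = s^2/x-bar, and the chi-square randomness test

    chi2 = I * (n - 1),

compared against the lower and upper quantiles of the chi-square distribution
with n - 1 degrees of freedom.  I below the lower limit indicates a uniform
(more even than random) arrangement, above the upper limit an aggregated one.
Counts may be expressed per trap or normalized to nymphs per 1,000 cm^2 of
sticky surface computed from tree diameter and band geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trapdata import Dataset, ensure_combined

logger = logging.getLogger(__name__)

RANDOM = "random"
UNIFORM = "uniform"
AGGREGATED = "aggregated"
UNCLASSIFIABLE = "unclassifiable"


class DegenerateSampleError(ValueError):
    """The statistic is undefined for this sample (e.g. zero mean)."""


@dataclass(frozen=True)
class DispersionSummary:
    """Dispersion statistics for one group of sampling units."""

    group_key: tuple
    n: int
    mean_density: float
    variance: float
    mean_crowding: float
    dispersion_index: float
    chi_square: float
    classification: str
    alpha: float = 0.05


def _mean_var(counts) -> tuple[np.ndarray, float, float]:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateSampleError("need at least 2 sampling units")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return x, float(x.mean()), float(x.var(ddof=1))


def mean_crowding(counts) -> float:
    """Lloyd's mean crowding m* = x-bar + (s^2/x-bar - 1).

    Sample variance uses the n-1 denominator, under which m* equals the mean
    exactly (in expectation) for Poisson counts.
    """
    _, mean, var = _mean_var(counts)
    if mean <= 0:
        raise DegenerateSampleError("mean crowding undefined for all-zero counts")
    return mean + (var / mean - 1.0)


def dispersion_test(counts, alpha: float = 0.05, group_key: tuple = ()) -> DispersionSummary:
    """Classify a group as random / uniform / aggregated via chi2 = I(n-1).

    ``alpha`` is the two-sided significance level; the test compares I(n-1)
    with the alpha/2 and 1-alpha/2 quantiles of chi-square with n-1 df.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x, mean, var = _mean_var(counts)
    if mean <= 0:
        raise DegenerateSampleError("dispersion index undefined for zero mean")
    n = x.size
    index = var / mean
    chi2 = index * (n - 1)
    lower = stats.chi2.ppf(alpha / 2, n - 1)
    upper = stats.chi2.ppf(1 - alpha / 2, n - 1)
    if chi2 < lower:
        cls = UNIFORM
    elif chi2 > upper:
        cls = AGGREGATED
    else:
        cls = RANDOM
    return DispersionSummary(
        group_key=tuple(group_key),
        n=int(n),
        mean_density=mean,
        variance=var,
        mean_crowding=mean + (var / mean - 1.0),
        dispersion_index=index,
        chi_square=chi2,
        classification=cls,
        alpha=alpha,
    )


def trap_area_cm2(
    dbh_cm: float,
    foam_width_cm: float,
    band_width_cm: float,
    *,
    foam_added_twice: bool = False,
) -> float:
    """Sticky-band surface area: pi * (DBH + foam) * band width, in cm^2.

    The foam spacer that holds the film off the bark is added once to the
    diameter by default (set ``foam_added_twice`` to add it on both sides).
    """
    if dbh_cm <= 0 or band_width_cm <= 0:
        raise ValueError("dbh_cm and band_width_cm must be positive")
    if foam_width_cm < 0:
        raise ValueError("foam_width_cm must be non-negative")
    eff = dbh_cm + (2.0 if foam_added_twice else 1.0) * foam_width_cm
    return math.pi * eff * band_width_cm


def normalize_per_1000cm2(count: float, area_cm2: float) -> float:
    """Convert a trap count to nymphs per 1,000 cm^2 of sticky surface."""
    if area_cm2 <= 0:
        raise ValueError("trap area must be positive")
    return count * 1000.0 / area_cm2


PER_TRAP = "per_trap"
PER_1000CM2 = "per_1000cm2"


def _unit_values(df: pd.DataFrame, unit: str) -> np.ndarray:
    if unit == PER_TRAP:
        return df["count"].to_numpy(dtype=float)
    if unit == PER_1000CM2:
        if df["dbh_cm"].isna().any() or df["band_width_cm"].isna().any():
            raise ValueError("per-area normalization needs dbh_cm and band_width_cm")
        areas = [
            trap_area_cm2(d, 0.0 if pd.isna(f) else f, b)
            for d, f, b in zip(df["dbh_cm"], df["foam_width_cm"], df["band_width_cm"])
        ]
        return np.array(
            [normalize_per_1000cm2(c, a) for c, a in zip(df["count"], areas)]
        )
    raise ValueError(f"unknown unit {unit!r}; use {PER_TRAP!r} or {PER_1000CM2!r}")


def classify_groups(
    ds: Dataset,
    unit: str = PER_TRAP,
    alpha: float = 0.05,
    instars: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dispersion summary per (site, date, instar) group plus a marginal tally.

    Returns ``(summaries, tally)``: one row per group with the
    :class:`DispersionSummary` fields, and a per-instar tally of how many
    groups were classified random / uniform / aggregated (groups whose mean is
    zero are counted as unclassifiable, not dropped).  Groups with fewer than
    two traps are skipped with a logged warning.
    """
    df = ensure_combined(ds).records
    if instars is not None:
        df = df[df["instar"].isin(instars)]
    rows = []
    for (site, date, instar), grp in df.groupby(["site", "date", "instar"], sort=True):
        if len(grp) < 2:
            logger.warning("group %s skipped: fewer than 2 traps", (site, date, instar))
            continue
        values = _unit_values(grp, unit)
        key = (site, date, instar)
        if values.mean() <= 0:
            rows.append(
                {
                    "site": site,
                    "date": date,
                    "instar": instar,
                    "n": len(grp),
                    "mean_density": 0.0,
                    "variance": 0.0,
                    "mean_crowding": np.nan,
                    "dispersion_index": np.nan,
                    "chi_square": np.nan,
                    "classification": UNCLASSIFIABLE,
                }
            )
            continue
        s = dispersion_test(values, alpha=alpha, group_key=key)
        rows.append(
            {
                "site": site,
                "date": date,
                "instar": instar,
                "n": s.n,
                "mean_density": s.mean_density,
                "variance": s.variance,
                "mean_crowding": s.mean_crowding,
                "dispersion_index": s.dispersion_index,
                "chi_square": s.chi_square,
                "classification": s.classification,
            }
        )
    summaries = pd.DataFrame(rows)
    if summaries.empty:
        return summaries, pd.DataFrame()
    tally = (
        summaries.pivot_table(
            index="instar",
            columns="classification",
            values="site",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=[RANDOM, UNIFORM, AGGREGATED, UNCLASSIFIABLE], fill_value=0)
        .rename_axis(columns=None)
        .reset_index()
    )
    return summaries, tally
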