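"""Seasonal structure of trap catches: rank stability and density decline.

Spearman rank correlations between dates quantify how long the relative
ranking of traps persists - the property that makes blocking on pretreatment
counts worthwhile.  The seasonal decline summary fits a negative-binomial
regression of per-trap counts on observation date as a factor; because the
model is saturated in date, the fitted marginal means equal the per-date
sample means, and Wald intervals on the log scale give asymmetric 95%
confidence bounds on the response scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._nb import nb2_regression
from .trapdata import Dataset, ensure_combined

logger = logging.getLogger(__name__)

BASELINE = "baseline_date"
PREVIOUS = "previous_date"


def _trap_matrix(ds: Dataset, instar: str) -> pd.DataFrame:
    """traps x dates matrix of counts for one instar (NaN where unobserved)."""
    df = ensure_combined(ds).records
    df = df[df["instar"] == instar]
    if df.empty:
        raise ValueError(f"no records for instar {instar!r}")
    return df.pivot_table(
        index=["site", "plot", "trap_id"], columns="date", values="count"
    )


def spearman_series(
    ds: Dataset,
    reference: str = BASELINE,
    instar: str = "combined",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rho of each date's trap counts against a reference date.

    ``baseline_date`` compares every later date with the first date;
    ``previous_date`` compares each date with the immediately preceding one.
    Traps missing on either date of a pair are dropped pairwise; dates with
    fewer than ``min_pairs`` common traps are flagged with rho = NaN.  Ties
    are handled by average ranks.
    """
    if reference not in (BASELINE, PREVIOUS):
        raise ValueError(f"reference must be {BASELINE!r} or {PREVIOUS!r}")
    mat = _trap_matrix(ds, instar)
    dates = list(mat.columns)
    if len(dates) < 2:
        raise ValueError("need at least 2 observation dates")
    rows = []
    for i, date in enumerate(dates[1:], start=1):
        ref_date = dates[0] if reference == BASELINE else dates[i - 1]
        pair = mat[[ref_date, date]].dropna()
        if len(pair) < min_pairs:
            rows.append(
                {"date": date, "reference_date": ref_date, "rho": np.nan,
                 "n_traps": len(pair), "flag": "too_few_traps"}
            )
            continue
        rho = stats.spearmanr(pair[ref_date], pair[date]).statistic
        rows.append(
            {"date": date, "reference_date": ref_date, "rho": float(rho),
             "n_traps": len(pair), "flag": ""}
        )
    out = pd.DataFrame(rows)
    out.attrs["reference"] = reference
    return out


def seasonal_decline(
    ds: Dataset,
    instar: str = "combined",
    level: float = 0.95,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Per-date NB marginal mean counts with Wald confidence intervals.

    Fits one negative-binomial regression with date as the only factor (one
    indicator per date, no intercept), so each coefficient is the log of that
    date's mean.  Dates with fewer than two traps, or with no catch at all,
    are dropped with a warning (a log-scale mean of zero counts is not
    estimable).  ``treatment`` optionally restricts to one treatment label
    (e.g. untreated controls).
    """
    df = ensure_combined(ds).records
    df = df[df["instar"] == instar]
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    keep = []
    for date, grp in df.groupby("date"):
        if len(grp) < 2:
            logger.warning("date %s dropped: fewer than 2 traps", date)
        elif grp["count"].sum() == 0:
            logger.warning("date %s dropped: no catch, log-mean not estimable", date)
        else:
            keep.append((date, grp))
    if not keep:
        raise ValueError("no usable dates")
    dates = [d for d, _ in keep]
    y = np.concatenate([g["count"].to_numpy(dtype=float) for _, g in keep])
    lengths = [len(g) for _, g in keep]
    X = np.zeros((len(y), len(keep)))
    start = 0
    for j, ln in enumerate(lengths):
        X[start : start + ln, j] = 1.0
        start += ln

    res = nb2_regression(y, X)
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for j, date in enumerate(dates):
        b, se = res.params[j], res.bse[j]
        rows.append(
            {
                "date": date,
                "n_traps": lengths[j],
                "mean": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
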