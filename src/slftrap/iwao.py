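"""Iwao patchiness regression: mean crowding regressed on mean density.

Each point is one group of sampling units (e.g. a site x date); the slope of
the ordinary least-squares line of mean crowding m* on mean density m measures
aggregation: slope 1 corresponds to a random (Poisson) arrangement, slope
significantly above 1 to aggregation, below 1 to a uniform arrangement.  For
negative-binomial counts with common size k the relation is exact:
m* = m (1 + 1/k), so the slope recovers 1 + 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dispersion import PER_TRAP, _unit_values, mean_crowding
from .trapdata import Dataset, ensure_combined


class SingularFitError(ValueError):
    """The design is degenerate (too few or collinear points)."""


@dataclass(frozen=True)
class IwaoFit:
    """OLS fit of mean crowding on mean density."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float | None
    r_squared: float
    f_value: float
    p_value: float
    df: int
    through_origin: bool
    n_points: int


@dataclass(frozen=True)
class AggregationTest:
    """t-test of the patchiness slope against 1 (the random/Poisson value)."""

    classification: str
    t_statistic: float
    p_value: float
    df: int
    alpha: float


def iwao_fit(points, through_origin: bool = False) -> IwaoFit:
    """Fit mean crowding on mean density by OLS.

    ``points`` is an iterable of ``(mean_density, mean_crowding)`` pairs.  The
    through-origin variant uses the no-intercept estimator sum(xy)/sum(x^2);
    its R^2 is computed on the uncentered total sum of squares, the
    convention under which forced fits report slightly higher R^2 because only
    one parameter is estimated.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (mean_density, mean_crowding) pairs")
    x, y = pts[:, 0], pts[:, 1]
    min_points = 2 if through_origin else 3
    if len(x) < min_points:
        raise SingularFitError(
            f"need at least {min_points} points ({'no ' if through_origin else ''}intercept fit)"
        )
    if not through_origin and np.ptp(x) == 0:
        raise SingularFitError("mean densities are all identical; slope is undefined")
    if through_origin and np.all(x == 0):
        raise SingularFitError("all mean densities zero; slope is undefined")

    design = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    with np.errstate(divide="ignore", invalid="ignore"):  # exact fits: mse_resid = 0
        f_value, f_pvalue = float(res.fvalue), float(res.f_pvalue)
        r_squared = float(res.rsquared)
    slope = float(res.params[-1])
    slope_se = float(res.bse[-1])
    if through_origin:
        intercept, intercept_se = 0.0, None
    else:
        intercept, intercept_se = float(res.params[0]), float(res.bse[0])
    return IwaoFit(
        slope=slope,
        slope_se=slope_se,
        intercept=intercept,
        intercept_se=intercept_se,
        r_squared=r_squared,
        f_value=f_value,
        p_value=f_pvalue,
        df=int(res.df_resid),
        through_origin=through_origin,
        n_points=len(x),
    )


def aggregation_inference(fit: IwaoFit, alpha: float = 0.05) -> AggregationTest:
    """Classify the population from the fitted slope via t = (b - 1) / se(b).

    Two-sided test of slope = 1; a significantly higher slope indicates an
    aggregated population, lower a uniform one, otherwise random.
    """
    if not np.isfinite(fit.slope_se) or fit.slope_se <= 0:
        raise SingularFitError("slope standard error is zero or undefined")
    t = (fit.slope - 1.0) / fit.slope_se
    p = 2.0 * stats.t.sf(abs(t), fit.df)
    if p < alpha:
        cls = "aggregated" if fit.slope > 1 else "uniform"
    else:
        cls = "random"
    return AggregationTest(
        classification=cls, t_statistic=float(t), p_value=float(p), df=fit.df, alpha=alpha
    )


def crowding_points(
    ds: Dataset,
    unit: str = PER_TRAP,
    group_keys: tuple[str, ...] = ("site", "date"),
    instar: str = "combined",
) -> pd.DataFrame:
    """(mean density, mean crowding) per group of traps, for one instar.

    Groups with fewer than two traps or zero mean are dropped (mean crowding
    is undefined there).
    """
    df = ensure_combined(ds).records
    df = df[df["instar"] == instar]
    rows = []
    for key, grp in df.groupby(list(group_keys), sort=True):
        if len(grp) < 2:
            continue
        values = _unit_values(grp, unit)
        if values.mean() <= 0:
            continue
        rows.append(
            {
                **dict(zip(group_keys, key if isinstance(key, tuple) else (key,))),
                "n": len(grp),
                "mean_density": float(values.mean()),
                "mean_crowding": mean_crowding(values),
            }
        )
    return pd.DataFrame(rows)


def fit_by_subset(
    ds: Dataset,
    subsets: Mapping[str, Callable[[pd.DataFrame], pd.Series]],
    unit: str = PER_TRAP,
    through_origin: bool = False,
    group_keys: tuple[str, ...] = ("site", "date"),
    instar: str = "combined",
) -> pd.DataFrame:
    """One Iwao fit per named record filter (pre/post-treatment comparisons).

    ``subsets`` maps a label to a boolean-mask function of the records frame;
    e.g. pretreatment dates only vs. the whole season.  Raises on an empty
    subset so a typo in a filter cannot silently yield a fit on no data.
    """
    rows = []
    for name, predicate in subsets.items():
        mask = predicate(ds.records)
        sub = ds.subset(mask)
        if len(sub) == 0:
            raise ValueError(f"subset {name!r} selects no records")
        pts = crowding_points(sub, unit=unit, group_keys=group_keys, instar=instar)
        min_points = 2 if through_origin else 3
        if len(pts) < min_points:
            raise SingularFitError(
                f"subset {name!r} yields {len(pts)} usable group(s); "
                f"need at least {min_points}"
            )
        fit = iwao_fit(pts[["mean_density", "mean_crowding"]].to_numpy(), through_origin)
        rows.append(
            {
                "subset": name,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
                "r_squared": fit.r_squared,
                "f_value": fit.f_value,
                "p_value": fit.p_value,
                "df": fit.df,
                "n_points": fit.n_points,
                "through_origin": through_origin,
            }
        )
    return pd.DataFrame(rows)
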