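"""Replication requirements to detect a proportional treatment reduction.

Counts are analysed on the log scale (ln(count + 1), the +1 guarding traps
that caught nothing).  A treatment that reduces mean counts by a proportion r
shifts the log-scale mean by j = ln(1 - r), so the standardized effect is
|j| / sigma, with sigma the between-plot SD of log counts estimated from
untreated control plots.  The smallest per-group sample size reaching the
requested power for a one-sided two-sample t-test is found from the
noncentral-t power function and rounded up (replication must meet or exceed
the target power, never undershoot it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

logger = logging.getLogger(__name__)


class InfiniteSampleSizeError(ValueError):
    """The effect is zero (or sigma is infinite); no finite n suffices."""


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for detecting a proportional reduction ``reduction_r``."""

    reduction_r: float
    sigma_log: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.reduction_r < 1:
            raise ValueError("reduction_r must be in (0, 1); r = 0 needs infinite n")
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")


def log_effect_shift(reduction_r: float) -> float:
    """Log-scale mean shift j = ln(1 - r) for a proportional decrease r."""
    if not 0 <= reduction_r < 1:
        raise ValueError("reduction must satisfy 0 <= r < 1")
    return math.log(1.0 - reduction_r)


def log_scale_sd(counts) -> float:
    """Sample SD (n-1 denominator) of ln(count + 1)."""
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 counts")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return float(np.log1p(x).std(ddof=1))


def qq_normality(counts) -> float:
    """Correlation of ordered ln(count+1) with normal plotting positions.

    A value near 1 supports the log-normality assumption behind the t-test
    power calculation (the numeric analogue of inspecting a Q-Q plot).
    """
    x = np.sort(np.log1p(np.asarray(counts, dtype=float)))
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 counts")
    if x.std() == 0:
        return float("nan")
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return float(np.corrcoef(x, q)[0, 1])


def replicates_required(spec: PowerSpec) -> int:
    """Smallest per-group n reaching ``spec.power`` for the one-sided t-test.

    Uses the noncentral-t power function of the two-sample pooled-variance
    test with equal group sizes and standardized effect |ln(1-r)| / sigma;
    the continuous solution is rounded up.
    """
    effect = abs(log_effect_shift(spec.reduction_r)) / spec.sigma_log
    if effect == 0:
        raise InfiniteSampleSizeError("zero effect size")
    n = TTestIndPower().solve_power(
        effect_size=effect,
        alpha=spec.alpha,
        power=spec.power,
        ratio=1.0,
        alternative="larger",
    )
    n_int = int(math.ceil(n - 1e-9))
    return max(n_int, 2)


def power_table(
    control_counts_by_date: dict,
    reductions,
    alpha: float = 0.05,
    power: float = 0.80,
) -> pd.DataFrame:
    """Replicates required per assessment date x proportional reduction.

    ``control_counts_by_date`` maps a date label to the untreated-control
    counts observed on that date; sigma is estimated from each date's counts
    on the log scale.  The output carries each date's raw-scale mean and SD
    alongside the requirement.  Dates with fewer than two counts are skipped
    with a warning; a date whose counts are all equal (sigma = 0) is kept but
    flagged with an infinite requirement.
    """
    reductions = list(reductions)
    if not reductions:
        raise ValueError("no reductions requested")
    rows = []
    for date, counts in control_counts_by_date.items():
        x = np.asarray(counts, dtype=float)
        if x.size < 2:
            logger.warning("date %s skipped: fewer than 2 control counts", date)
            continue
        sigma = log_scale_sd(x)
        qq = qq_normality(x) if x.size >= 3 else float("nan")
        for r in reductions:
            if sigma == 0:
                n_req: float = float("inf")
                flag = "zero_variance"
            else:
                n_req = replicates_required(
                    PowerSpec(reduction_r=r, sigma_log=sigma, alpha=alpha, power=power)
                )
                flag = ""
            rows.append(
                {
                    "date": date,
                    "reduction_r": r,
                    "n_required": n_req,
                    "mean_raw": float(x.mean()),
                    "sd_raw": float(x.std(ddof=1)),
                    "sigma_log": sigma,
                    "qq_correlation": qq,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)
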