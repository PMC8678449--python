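"""Enumerative sample-size curves and sampling labor costs.

The number of sampling units q needed to estimate a mean density x with
proportional precision d (SE of the mean over the mean) follows from the
patchiness-regression intercept alpha and slope beta:

    q = (t^2 / d^2) * [ (alpha + 1) / x + (beta - 1) ]

For an aggregated population (beta > 1) q levels off at t^2/d^2 * (beta - 1)
as density grows, so the required effort is nearly constant across the
densities seen in the field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Parameters of the enumerative sample-size formula.

    ``t`` defaults to 1.96 (normal-approximation Student's t at P = 0.05);
    ``d`` is the desired proportional precision, e.g. 0.20 for a standard
    error of 20% of the mean; ``alpha_int``/``beta_slope`` come from the
    regression of mean crowding on mean density.
    """

    beta_slope: float
    alpha_int: float = 0.0
    d: float = 0.20
    t: float = 1.96

    def __post_init__(self) -> None:
        if not 0 < self.d < 1:
            raise ValueError("precision d must be in (0, 1)")
        if self.t <= 0:
            raise ValueError("t must be positive")


def _round_half_up(q: float) -> int:
    return int(math.floor(q + 0.5))


def sample_number(spec: SampleSizeSpec, mean_density: float) -> int:
    """Sampling units needed to estimate ``mean_density`` at precision d.

    The continuous value is rounded to the nearest integer (half up); a
    non-positive result (possible for beta < 1 at high density) is reported
    as the minimum of one sample, with a warning.
    """
    if mean_density <= 0:
        raise ValueError("mean density must be positive")
    q = (spec.t**2 / spec.d**2) * (
        (spec.alpha_int + 1.0) / mean_density + (spec.beta_slope - 1.0)
    )
    if q <= 0:
        logger.warning(
            "sample number %.3f <= 0 at density %g; reporting minimum of 1", q, mean_density
        )
        return 1
    return max(1, _round_half_up(q))


def sample_number_curve(
    param_sets: dict[str, tuple[float, float]],
    densities,
    precisions,
    t: float = 1.96,
) -> pd.DataFrame:
    """Full grid of sample numbers over density x precision x parameter set.

    ``param_sets`` maps a column label (e.g. a site/unit combination) to an
    ``(alpha_int, beta_slope)`` pair.  Returns a frame indexed by density with
    a (precision, label) column MultiIndex - the layout of a sample-number
    table with densities as rows.
    """
    densities = list(densities)
    precisions = list(precisions)
    if not densities or not precisions or not param_sets:
        raise ValueError("empty density, precision, or parameter-set grid")
    if any(x <= 0 for x in densities):
        raise ValueError("all densities must be positive")
    columns = pd.MultiIndex.from_tuples(
        [(d, label) for d in precisions for label in param_sets],
        names=["precision", "params"],
    )
    table = pd.DataFrame(index=pd.Index(densities, name="mean_density"), columns=columns)
    for d in precisions:
        for label, (alpha_int, beta_slope) in param_sets.items():
            spec = SampleSizeSpec(beta_slope=beta_slope, alpha_int=alpha_int, d=d, t=t)
            table[(d, label)] = [sample_number(spec, x) for x in densities]
    return table.astype(int)


def labor_cost(minutes_per_trap: float, wage_per_hour: float, n_traps: int) -> float:
    """Personnel cost of servicing ``n_traps``, rounded to cents.

    cost = n_traps * (minutes_per_trap / 60) * wage_per_hour
    """
    if minutes_per_trap < 0 or wage_per_hour < 0 or n_traps < 0:
        raise ValueError("labor-cost inputs must be non-negative")
    cost = Decimal(n_traps) * Decimal(str(minutes_per_trap)) / Decimal(60) * Decimal(
        str(wage_per_hour)
    )
    return float(cost.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
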