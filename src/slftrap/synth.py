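"""Synthetic trap-count generator with the field data's statistical structure.

Counts are negative binomial around a per-trap latent intensity that makes
traps persistently "good" or "bad":

* per-trap log-normal multiplier, evolving across dates as a stationary
  AR(1) on the log scale (persistence ``trap_autocorr``), mean 1;
* a seasonal exponential decline of the baseline mean (``decline_rate`` per
  day), mimicking the observed drop in catches over the nymphal season;
* NB size ``nb_size_k`` (quadratic parameterization), chosen because it
  yields the exact patchiness identity m* = m (1 + 1/k), so the Iwao slope
  on generated data has the known target 1 + 1/k; ``nb_size_k = inf`` gives
  Poisson (random) counts;
* an optional multiplicative treatment effect (1 - r) on a random fraction
  of traps;
* a static multinomial split of each total into the four instars.

Everything is driven by one seeded generator with a fixed draw order, so a
given config reproduces its Dataset exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._nb import QUADRATIC, nb_draw
from .trapdata import CANONICAL_COLUMNS, Dataset


def _default_dates() -> list[dt.date]:
    start = dt.date(2020, 6, 11)
    return [start + dt.timedelta(days=3 * i) for i in range(12)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror a mid-season rural trapping campaign: 6 sites of 15
    traps observed every 3 days, starting around 100 nymphs per trap and
    declining ~5%/day, aggregation k = 2 (patchiness slope 1.5, inside the
    1.4-2.6 range seen on sticky bands), trap rank persistence 0.8 between
    consecutive dates.
    """

    n_sites: int = 6
    traps_per_site: int = 15
    dates: tuple = field(default_factory=lambda: tuple(_default_dates()))
    baseline_mean: float = 100.0
    nb_size_k: float = 2.0
    decline_rate: float = 0.05
    trap_autocorr: float = 0.8
    trap_sd_log: float = 0.5
    treatment_effect_r: float = 0.0
    treated_fraction: float = 0.0
    instar_mixture: tuple = (0.4, 0.3, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.traps_per_site < 1:
            raise ValueError("need at least one site and one trap per site")
        if len(self.dates) < 1:
            raise ValueError("need at least one date")
        if self.baseline_mean <= 0 or self.nb_size_k <= 0:
            raise ValueError("baseline_mean and nb_size_k must be positive")
        if self.decline_rate < 0:
            raise ValueError("decline_rate must be non-negative")
        if not 0 <= self.trap_autocorr < 1:
            raise ValueError("trap_autocorr must be in [0, 1)")
        if self.trap_sd_log < 0:
            raise ValueError("trap_sd_log must be non-negative")
        if not 0 <= self.treatment_effect_r < 1:
            raise ValueError("treatment_effect_r must be in [0, 1)")
        if not 0 <= self.treated_fraction <= 1:
            raise ValueError("treated_fraction must be in [0, 1]")
        if len(self.instar_mixture) != 4:
            raise ValueError("instar_mixture needs 4 proportions")
        if abs(sum(self.instar_mixture) - 1.0) > 1e-9:
            raise ValueError("instar_mixture must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dates"] = [str(x) for x in self.dates]
        d["instar_mixture"] = list(self.instar_mixture)
        return d


def generate(config: SyntheticConfig) -> Dataset:
    """Generate a tidy trap-count Dataset under ``config``.

    Rows are emitted for instars 1-4 and an explicit ``combined`` total per
    trap x date.  Trap geometry (DBH ~ N(17.6, 4.7) cm clipped at 5 cm, 7.6
    cm band, 2 cm foam spacer) matches typical sticky-band installations on
    mid-sized host trees.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_traps = config.n_sites * config.traps_per_site
    dates = sorted(pd.Timestamp(d) for d in config.dates)
    days = np.array([(d - dates[0]).days for d in dates], dtype=float)
    n_dates = len(dates)

    dbh = np.clip(rng.normal(17.6, 4.7, size=n_traps), 5.0, None)
    treated = rng.random(n_traps) < config.treated_fraction

    # stationary AR(1) latent log-intensity, sd trap_sd_log, mean-1 multiplier
    sigma, a = config.trap_sd_log, config.trap_autocorr
    z = np.empty((n_traps, n_dates))
    z[:, 0] = rng.normal(0.0, 1.0, size=n_traps)
    for j in range(1, n_dates):
        z[:, j] = a * z[:, j - 1] + np.sqrt(1 - a * a) * rng.normal(0.0, 1.0, size=n_traps)
    mult = np.exp(sigma * z - sigma * sigma / 2.0)

    base = config.baseline_mean * np.exp(-config.decline_rate * days)  # per date
    mean = base[None, :] * mult
    mean[treated, :] *= 1.0 - config.treatment_effect_r

    totals = nb_draw(rng, mean, config.nb_size_k, QUADRATIC)
    mixture = np.asarray(config.instar_mixture, dtype=float)
    # multinomial split per trap x date, fixed iteration order
    instar_counts = np.zeros((n_traps, n_dates, 4), dtype=np.int64)
    for i in range(n_traps):
        for j in range(n_dates):
            instar_counts[i, j] = rng.multinomial(totals[i, j], mixture)

    rows = []
    trap_meta = []
    for s in range(config.n_sites):
        for t in range(config.traps_per_site):
            trap_meta.append(
                (
                    f"S{s + 1:02d}",
                    f"S{s + 1:02d}-P{t // 2 + 1:02d}",
                    f"S{s + 1:02d}-T{t + 1:02d}",
                )
            )
    for i, (site, plot, trap_id) in enumerate(trap_meta):
        for j, date in enumerate(dates):
            common = {
                "site": site,
                "plot": plot,
                "trap_id": trap_id,
                "date": date,
                "dbh_cm": round(float(dbh[i]), 1),
                "band_width_cm": 7.6,
                "foam_width_cm": 2.0,
                "treatment": "treated" if treated[i] else "control",
            }
            for k in range(4):
                rows.append({**common, "instar": str(k + 1), "count": int(instar_counts[i, j, k])})
            rows.append({**common, "instar": "combined", "count": int(totals[i, j])})

    df = pd.DataFrame(rows)[CANONICAL_COLUMNS]
    return Dataset(df, metadata={"generator": "slftrap.synth.generate", "config": config.to_dict()})


def generate_pretreatment_pairs(
    config: SyntheticConfig,
    n_plots: int,
    projection_slope: float = 0.8,
    projection_dispersion: float = 5.0,
):
    """Correlated (pretreatment, null posttreatment) plot counts.

    Pretreatment counts are NB(baseline_mean, nb_size_k); each posttreatment
    count is an NB draw with mean ``projection_slope`` x pretreatment count
    and quadratic dispersion ``projection_dispersion`` - the projection model
    the design simulator assumes, with no treatment applied.  Intended as a
    pipeline fixture for end-to-end design-simulation tests.
    """
    if n_plots < 2 or n_plots % 2:
        raise ValueError("n_plots must be an even number >= 2")
    if projection_slope <= 0 or projection_dispersion <= 0:
        raise ValueError("projection slope and dispersion must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pre = nb_draw(
        rng, np.full(n_plots, config.baseline_mean), config.nb_size_k, QUADRATIC
    )
    post = nb_draw(rng, projection_slope * pre.astype(float), projection_dispersion, QUADRATIC)
    return pre, post
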