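import numpy as np
import pandas as pd
import pytest

from slftrap import SyntheticConfig, generate
from slftrap.trapdata import from_records


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured synthetic season: 3 sites x 8 traps x 6 dates."""
    cfg = SyntheticConfig(
        n_sites=3,
        traps_per_site=8,
        dates=tuple(pd.date_range("2020-06-11", periods=6, freq="3D").date),
        baseline_mean=60.0,
        nb_size_k=2.0,
        decline_rate=0.04,
        trap_autocorr=0.8,
        trap_sd_log=0.5,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture()
def tiny_dataset():
    """Hand-written 2-site dataset with known counts, one date, combined only."""
    rows = []
    for site, counts in [("A", [3, 3, 3, 3]), ("B", [0, 1, 2, 9])]:
        for i, c in enumerate(counts):
            rows.append(
                {
                    "site": site,
                    "plot": f"{site}P1",
                    "trap_id": f"{site}T{i + 1}",
                    "date": "2020-06-11",
                    "instar": "combined",
                    "count": c,
                    "dbh_cm": 17.6,
                    "band_width_cm": 7.6,
                    "foam_width_cm": 2.0,
                    "treatment": "control",
                }
            )
    return from_records(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
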