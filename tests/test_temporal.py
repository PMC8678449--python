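"""Rank-correlation series and the seasonal NB marginal-mean summary."""

import numpy as np
import pandas as pd
import pytest

from slftrap.synth import SyntheticConfig, generate
from slftrap.temporal import BASELINE, PREVIOUS, seasonal_decline, spearman_series
from slftrap.trapdata import from_records


def _dataset_from_matrix(counts_by_date: dict[str, list[int]]):
    """Build a Dataset from {date: counts aligned by trap index}."""
    rows = []
    for date, counts in counts_by_date.items():
        for i, c in enumerate(counts):
            rows.append(
                {"site": "A", "plot": "P", "trap_id": f"T{i}", "date": date,
                 "instar": "combined", "count": c}
            )
    return from_records(pd.DataFrame(rows))


class TestSpearmanSeries:
    def test_identical_counts_give_rho_one(self):
        ds = _dataset_from_matrix(
            {"2020-06-11": [3, 1, 4, 1, 5], "2020-06-14": [3, 1, 4, 1, 5]}
        )
        out = spearman_series(ds, reference=BASELINE)
        assert out["rho"].tolist() == [pytest.approx(1.0)]

    def test_reversed_ranking_gives_minus_one(self):
        ds = _dataset_from_matrix(
            {"2020-06-11": [1, 2, 3, 4, 5], "2020-06-14": [50, 40, 30, 20, 10]}
        )
        out = spearman_series(ds, reference=BASELINE)
        assert out["rho"].tolist() == [pytest.approx(-1.0)]

    def test_hand_ranked_oracle_with_ties(self):
        """rho from explicit average-rank computation, independent of scipy."""
        x, y = [3, 1, 4, 1, 5], [2, 7, 1, 8, 2]

        def avg_ranks(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = float(np.corrcoef(rx, ry)[0, 1])
        ds = _dataset_from_matrix({"2020-06-11": x, "2020-06-14": y})
        out = spearman_series(ds, reference=BASELINE)
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        x, y = [3, 1, 4, 1, 5], [2, 7, 1, 8, 2]
        ds1 = _dataset_from_matrix({"2020-06-11": x, "2020-06-14": y})
        ds2 = _dataset_from_matrix(
            {"2020-06-11": [v**2 for v in x], "2020-06-14": [v * 10 + 1 for v in y]}
        )
        r1 = spearman_series(ds1, reference=BASELINE)["rho"].iloc[0]
        r2 = spearman_series(ds2, reference=BASELINE)["rho"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_previous_mode_uses_prior_date(self):
        ds = _dataset_from_matrix(
            {
                "2020-06-11": [1, 2, 3, 4, 5],
                "2020-06-14": [5, 4, 3, 2, 1],
                "2020-06-17": [1, 2, 3, 4, 5],
            }
        )
        out = spearman_series(ds, reference=PREVIOUS)
        assert out["rho"].tolist() == [pytest.approx(-1.0), pytest.approx(-1.0)]
        assert out["reference_date"].tolist() == list(pd.to_datetime(
            ["2020-06-11", "2020-06-14"]
        ))

    def test_too_few_common_traps_flagged(self):
        rows = [
            {"site": "A", "plot": "P", "trap_id": f"T{i}", "date": "2020-06-11",
             "instar": "combined", "count": i} for i in range(5)
        ] + [
            {"site": "A", "plot": "P", "trap_id": "T0", "date": "2020-06-14",
             "instar": "combined", "count": 3},
            {"site": "A", "plot": "P", "trap_id": "T1", "date": "2020-06-14",
             "instar": "combined", "count": 4},
        ]
        ds = from_records(pd.DataFrame(rows))
        out = spearman_series(ds, reference=BASELINE)
        assert out["flag"].iloc[0] == "too_few_traps"
        assert np.isnan(out["rho"].iloc[0])

    def test_baseline_declines_faster_than_previous_on_ar1_data(self):
        """Rank persistence: consecutive-date rho stays high while the
        correlation with the first date decays with lag."""
        cfg = SyntheticConfig(
            n_sites=2, traps_per_site=40,
            dates=tuple(pd.date_range("2020-06-11", periods=10, freq="3D").date),
            baseline_mean=80.0, nb_size_k=4.0, decline_rate=0.0,
            trap_autocorr=0.6, trap_sd_log=1.0, seed=77,
        )
        ds = generate(cfg)
        base = spearman_series(ds, reference=BASELINE)
        prev = spearman_series(ds, reference=PREVIOUS)
        assert base["rho"].iloc[-1] < prev["rho"].median()


class TestSeasonalDecline:
    def test_saturated_model_recovers_per_date_means(self):
        rng = np.random.default_rng(3)
        counts = {
            "2020-06-11": rng.negative_binomial(4, 4 / 54, size=30).tolist(),
            "2020-06-14": rng.negative_binomial(4, 4 / 34, size=30).tolist(),
            "2020-06-17": rng.negative_binomial(4, 4 / 14, size=30).tolist(),
        }
        ds = _dataset_from_matrix(counts)
        out = seasonal_decline(ds).set_index("date")
        for date, vals in counts.items():
            fitted = out.loc[pd.Timestamp(date), "mean"]
            assert fitted == pytest.approx(np.mean(vals), rel=1e-3)

    def test_flat_counts_give_flat_means_overlapping_cis(self):
        ds = _dataset_from_matrix(
            {"2020-06-11": [5] * 10 + [7] * 10, "2020-06-14": [7] * 10 + [5] * 10}
        )
        out = seasonal_decline(ds)
        assert out["mean"].iloc[0] == pytest.approx(out["mean"].iloc[1])
        assert out["ci_low"].iloc[0] < out["mean"].iloc[1] < out["ci_high"].iloc[0]

    def test_declining_generator_yields_decreasing_means(self):
        cfg = SyntheticConfig(
            n_sites=2, traps_per_site=30,
            dates=tuple(pd.date_range("2020-06-11", periods=6, freq="3D").date),
            baseline_mean=120.0, nb_size_k=5.0, decline_rate=0.12,
            trap_autocorr=0.0, trap_sd_log=0.2, seed=21,
        )
        out = seasonal_decline(generate(cfg))
        means = out.sort_values("date")["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)
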