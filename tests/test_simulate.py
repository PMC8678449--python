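"""Design-simulator components: NB fits, assignment, projection, analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slftrap.simulate import (
    CRD,
    RCBD,
    NBFit,
    analyze_experiment,
    assign_designs,
    fit_nb,
    power_grid,
    project_posttreatment,
    threshold_map,
)


class TestFitNB:
    def test_parameter_recovery_linear(self):
        rng = np.random.default_rng(7)
        # NB with mean 50, variance 250 -> linear phi = 4
        k = 50 / 4
        y = rng.negative_binomial(k, k / (k + 50), size=800)
        fit = fit_nb(y, "linear")
        se_mean = np.sqrt(y.var(ddof=1) / y.size)
        assert abs(fit.mean - 50) < 3 * se_mean + abs(fit.mean - y.mean()) + 1e-9
        assert fit.variance / fit.mean == pytest.approx(5.0, rel=0.25)

    def test_parameter_recovery_quadratic(self):
        rng = np.random.default_rng(8)
        y = rng.negative_binomial(3.0, 3.0 / (3.0 + 40.0), size=800)
        fit = fit_nb(y, "quadratic")
        assert fit.mean == pytest.approx(y.mean())
        assert fit.dispersion == pytest.approx(3.0, rel=0.3)

    def test_near_poisson_pinned_with_warning(self, caplog):
        rng = np.random.default_rng(9)
        y = rng.poisson(2.0, size=40)
        while y.var(ddof=1) > y.mean():  # ensure boundary case
            y = rng.poisson(2.0, size=40)
        with caplog.at_level("WARNING"):
            fit = fit_nb(y, "linear")
        assert fit.dispersion == 0.0
        assert any("Poisson" in rec.message for rec in caplog.records)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            fit_nb([1, 2, 3], "linear")  # too few
        with pytest.raises(ValueError):
            fit_nb([1.5, 2, 3, 4, 5], "linear")  # non-integer


class TestAssignDesigns:
    def test_blocking_structure_is_deterministic(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            _, rcbd, blocks = assign_designs([10, 9, 8, 7], rng)
            assert blocks.tolist() == [0, 0, 1, 1]  # {10,9} then {8,7}
            assert rcbd.sum() == 2

    def test_crd_arms_equal_any_size(self):
        rng = np.random.default_rng(1)
        for m in (4, 10, 26):
            crd, _, _ = assign_designs(np.arange(m), rng)
            assert crd.sum() == m // 2

    def test_each_plot_treated_half_the_time(self):
        rng = np.random.default_rng(2)
        m, reps = 8, 4000
        counts = np.array([50, 40, 30, 20, 10, 5, 2, 1])
        freq = np.zeros((2, m))
        for _ in range(reps):
            crd, rcbd, _ = assign_designs(counts, rng)
            freq[0] += crd
            freq[1] += rcbd
        freq /= reps
        assert np.all(np.abs(freq - 0.5) < 0.03)

    def test_odd_plot_count_rejected(self):
        with pytest.raises(ValueError):
            assign_designs([3, 2, 1], np.random.default_rng(0))


class TestProjection:
    def test_full_reduction_zeroes_treated(self):
        rng = np.random.default_rng(3)
        init = np.array([50, 40, 30, 20])
        treated = np.array([True, False, True, False])
        post = project_posttreatment(init, treated, 0.8, 5.0, 1.0 - 1e-12, rng)
        assert (post[treated] == 0).all()

    def test_zero_init_is_deterministic_zero(self):
        rng = np.random.default_rng(4)
        post = project_posttreatment([0, 0, 10, 10], [False] * 4, 0.8, 5.0, 0.0, rng)
        assert post[0] == post[1] == 0

    def test_control_moment(self):
        rng = np.random.default_rng(5)
        n = 100_000
        post = project_posttreatment(
            np.full(n, 100.0), np.zeros(n, dtype=bool), 0.8, 5.0, 0.0, rng
        )
        se = post.std() / np.sqrt(n)
        assert abs(post.mean() - 80.0) < 4 * se

    def test_null_reduction_arms_exchangeable(self):
        rng = np.random.default_rng(6)
        n = 5000
        treated = np.zeros(2 * n, dtype=bool)
        treated[:n] = True
        post = project_posttreatment(
            np.full(2 * n, 60.0), treated, 0.8, 5.0, 0.0, rng
        )
        ks = stats.ks_2samp(post[:n], post[n:])
        assert ks.pvalue > 0.01


class TestAnalyzeExperiment:
    def test_separation_is_significant(self):
        y = np.array([0, 0, 0, 0, 55, 60, 48, 70])
        t = np.array([True] * 4 + [False] * 4)
        res = analyze_experiment(y, t, design=CRD)
        assert res.significant and res.flag == "separation"

    def test_identical_arms_not_significant(self):
        y = np.array([10, 12, 9, 11] * 2)
        t = np.array([True] * 4 + [False] * 4)
        assert not analyze_experiment(y, t, design=CRD).significant

    def test_all_zero_experiment_degenerate(self):
        y = np.zeros(8)
        t = np.array([True] * 4 + [False] * 4)
        res = analyze_experiment(y, t, design=CRD)
        assert not res.significant and res.flag == "degenerate"

    def test_rcbd_requires_blocks(self):
        y = np.arange(8)
        t = np.array([True, False] * 4)
        with pytest.raises(ValueError, match="block"):
            analyze_experiment(y, t, design=RCBD)

    @pytest.mark.parametrize("block_effects", ["random", "fixed"])
    def test_rcbd_detects_strong_reduction(self, block_effects):
        rng = np.random.default_rng(10)
        init = rng.negative_binomial(12.5, 12.5 / 62.5, size=16)
        _, rcbd, blocks = assign_designs(init, rng)
        post = project_posttreatment(init, rcbd, 0.8, 5.0, 0.85, rng)
        res = analyze_experiment(post, rcbd, design=RCBD, blocks=blocks,
                                 block_effects=block_effects)
        assert res.significant


@pytest.fixture(scope="module")
def small_grid():
    return power_grid(
        NBFit(50.0, 4.0, "linear"), 0.8, 5.0,
        n_replicates_list=[4], reductions=[0.0, 0.85],
        n_sims=60, seed=99,
    )


class TestPowerGrid:
    def test_every_cell_present_once(self, small_grid):
        t = small_grid.table
        assert len(t) == 4  # 1 n x 2 r x 2 designs
        assert t.duplicated(["n_replicates", "reduction_r", "design"]).sum() == 0

    def test_high_reduction_beats_null(self, small_grid):
        by = small_grid.table.set_index(["reduction_r", "design"])["power"]
        for design in (CRD, RCBD):
            assert by[(0.85, design)] > by[(0.0, design)] + 0.3

    def test_same_seed_reproduces_bitwise(self, small_grid):
        again = power_grid(
            NBFit(50.0, 4.0, "linear"), 0.8, 5.0,
            n_replicates_list=[4], reductions=[0.0, 0.85],
            n_sims=60, seed=99,
        )
        pd.testing.assert_frame_equal(small_grid.table, again.table)
        assert small_grid.table.to_csv() == again.table.to_csv()

    def test_threshold_map_categories(self, small_grid):
        cells = threshold_map(small_grid, power_target=0.8)
        assert set(cells.to_numpy().ravel()) <= {
            "both", "blocked_only", "random_only", "neither"
        }
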