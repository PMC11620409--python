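"""Statistical battery: check-loss oracle, permutation inference, sum-of-LR,
Spearman precision, and the study summary."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pxrfkit import stats
from pxrfkit.stats import (
    ComparisonSkipped,
    PrecisionResult,
    TestResult as ComparisonResult,
    bh_adjust,
    manyglm_overall,
    median_permutation_test,
    median_regression_binary,
    pairwise_comparisons,
    replicate_precision,
    summarize_study,
)


def check_loss(y, x, b0, b1):
    return np.sum(np.abs(y - (b0 + b1 * x))) / 2.0


class TestMedianRegression:
    def test_worked_example(self):
        intercept, slope = median_regression_binary(
            [1, 2, 3, 4, 5, 9], ["a"] * 3 + ["b"] * 3
        )
        assert (intercept, slope) == (2.0, 3.0)

    def test_identical_groups_zero_slope(self):
        _, slope = median_regression_binary([5, 6, 7, 5, 6, 7], [0, 0, 0, 1, 1, 1])
        assert slope == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-50, 50))
    def test_location_equivariance(self, c):
        y = np.array([1.0, 4.0, 2.0, 8.0, 3.0, 9.0, 7.0])
        g = np.array([0, 0, 0, 1, 1, 1, 1])
        b0, b1 = median_regression_binary(y, g)
        b0c, b1c = median_regression_binary(y + c, g)
        assert b0c == pytest.approx(b0 + c)
        assert b1c == pytest.approx(b1)

    def test_matches_check_loss_grid_minimum(self, rng):
        """The group-median fit attains the tau=0.5 check-loss minimum over
        a grid of candidate (intercept, slope) pairs built from the data."""
        for _ in range(100):
            n1, n2 = rng.integers(2, 7, size=2)
            y1 = np.round(rng.normal(0, 3, n1), 2)
            y2 = np.round(rng.normal(1, 3, n2), 2)
            y = np.concatenate([y1, y2])
            x = np.repeat([0, 1], [n1, n2])
            b0, b1 = median_regression_binary(y, x)
            ours = check_loss(y, x, b0, b1)
            best = min(
                check_loss(y, x, c0, m2 - c0) for c0 in y for m2 in y
            )
            assert ours <= best + 1e-9

    def test_empty_level_rejected(self):
        with pytest.raises(ValueError):
            median_regression_binary([1.0, 2.0], ["a", "a"])

    def test_agrees_with_statsmodels_quantreg(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            n1, n2 = rng.integers(3, 9, size=2)
            y = np.concatenate([rng.normal(0, 2, n1), rng.normal(1.5, 2, n2)])
            x = np.repeat([0.0, 1.0], [n1, n2])
            b0, b1 = median_regression_binary(y, x)
            fit = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.5)
            # both minimise the same check loss; compare attained losses
            # (the minimiser itself can be an interval for even group sizes)
            ours = check_loss(y, x, b0, b1)
            theirs = check_loss(y, x, fit.params[0], fit.params[1])
            assert ours <= theirs + 1e-6


def exact_permutation_p(y1, y2):
    """Exact tie-inclusive permutation p-value of |median difference| by
    full enumeration of group assignments."""
    pooled = np.concatenate([y1, y2])
    n1 = len(y1)
    observed = abs(np.median(y2) - np.median(y1))
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        stat = abs(np.median(pooled[~mask]) - np.median(pooled[mask]))
        count += stat >= observed - 1e-12
        total += 1
    return count / total


class TestMedianPermutationTest:
    def test_constant_data_gives_p_one(self):
        res = median_permutation_test([3.0] * 8, [0] * 4 + [1] * 4, n_perm=199, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_degenerate_two_point_data_is_insensitive(self):
        # all 5/5 splits of {0 x5, 10 x5} give |median diff| = 10, so the
        # exact permutation p is 1: the median cannot separate these groups
        y1, y2 = np.zeros(5), np.full(5, 10.0)
        assert exact_permutation_p(y1, y2) == 1.0
        res = median_permutation_test(
            np.concatenate([y1, y2]), np.repeat([0, 1], 5), n_perm=999, seed=3
        )
        assert res.p_value == 1.0

    def test_matches_exact_enumeration(self):
        y1 = np.array([0.0, 1.0, 2.0, 2.5])
        y2 = np.array([5.0, 6.0, 9.0, 7.5])
        p_exact = exact_permutation_p(y1, y2)
        res = median_permutation_test(
            np.concatenate([y1, y2]), np.repeat([0, 1], 4), n_perm=4999, seed=11
        )
        # sampled null with 4999 draws sits within Monte-Carlo error
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_deterministic_given_seed(self, rng):
        y = rng.normal(size=14)
        g = np.repeat([0, 1], 7)
        r1 = median_permutation_test(y, g, n_perm=199, seed=5)
        r2 = median_permutation_test(y, g, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value

    def test_insufficient_observations_skipped(self):
        with pytest.raises(ComparisonSkipped):
            median_permutation_test([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], n_perm=99)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        runs = 300
        for i in range(runs):
            y = rng.lognormal(0, 1, 20)
            res = median_permutation_test(y, np.repeat([0, 1], 10), n_perm=199, seed=i)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / runs <= 0.09


class TestPairwise:
    def test_three_level_factor_gives_three_comparisons(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(["head", "leg", "tail"], 10)
        results = pairwise_comparisons(y, g, n_perm=199, seed=0, factor="location")
        assert len(results) == 3
        assert {r.comparison for r in results} == {
            "head vs leg", "head vs tail", "leg vs tail",
        }
        for r in results:
            assert r.p_adjusted >= r.p_value - 1e-12

    def test_two_levels_adjustment_is_identity(self, rng):
        y = rng.normal(size=12)
        g = np.repeat([0, 1], 6)
        (res,) = pairwise_comparisons(y, g, n_perm=199, seed=0)
        assert res.p_adjusted == res.p_value

    def test_four_scan_times_give_six_comparisons(self, rng):
        y = rng.normal(size=40)
        g = np.repeat([20, 40, 60, 80], 10)
        assert len(pairwise_comparisons(y, g, n_perm=199, seed=0)) == 6


class TestManyGLM:
    def test_hand_rss_oracle(self):
        Y = np.array([[1, 2], [2, 3], [3, 4], [5, 6], [6, 7], [7, 8]], float)
        g = ["A"] * 3 + ["B"] * 3
        res = manyglm_overall(Y, g, transform="none", n_perm=99, seed=0)
        # per column RSS0 = 28, RSS1 = 4: LR = 6 ln 7 each
        assert res.statistic == pytest.approx(2 * 6 * np.log(7.0), rel=1e-12)
        assert res.scope == "overall"

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            manyglm_overall(np.ones((4, 2)), ["A"] * 4, n_perm=99)

    def test_zero_variance_column_dropped(self, rng):
        Y = np.column_stack([rng.normal(size=8), np.full(8, 3.0)])
        res = manyglm_overall(Y, np.repeat([0, 1], 4), transform="none",
                              n_perm=99, seed=0)
        assert np.isfinite(res.statistic)

    def test_all_columns_degenerate_rejected(self):
        Y = np.full((6, 2), 5.0)
        with pytest.raises(ValueError):
            manyglm_overall(Y, np.repeat([0, 1], 3), transform="none", n_perm=99)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        runs = 300
        for i in range(runs):
            Y = rng.standard_normal((20, 5))
            res = manyglm_overall(Y, np.repeat([0, 1], 10), transform="none",
                                  n_perm=199, seed=i)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / runs <= 0.09

    def test_detects_large_shift(self, rng):
        Y = rng.standard_normal((20, 5))
        Y[10:] += 2.0
        res = manyglm_overall(Y, np.repeat([0, 1], 10), transform="none",
                              n_perm=199, seed=0)
        assert res.p_value <= 0.01


def _replicate_table(x, y, element="Fe"):
    rows = []
    for rep, vals in ((1, x), (2, y)):
        for i, v in enumerate(vals):
            rows.append({"specimen_id": f"s{i}", "taxon": "fish", "location": "body",
                         "state": "thawed", "dwell_time_s": 80.0, "backed": False,
                         "element": element, "replicate": rep,
                         "concentration_pct": v})
    return pd.DataFrame(rows)


class TestReplicatePrecision:
    def test_identical_replicates_give_rho_one(self):
        table = _replicate_table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = replicate_precision(table)
        assert all(r.rho == pytest.approx(1.0) for r in res)

    def test_rank_formula_oracle(self):
        # x=(1,2,3,4), y=(1,3,2,4): sum d^2 = 2 -> rho = 1 - 12/60 = 0.8
        table = _replicate_table([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0])
        res = replicate_precision(table)
        per_fe = [r for r in res if r.scope == "Fe"][0]
        assert per_fe.rho == pytest.approx(0.8)
        assert per_fe.n_pairs == 4

    def test_reversed_order_gives_minus_one(self):
        table = _replicate_table([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0])
        res = replicate_precision(table)
        assert [r for r in res if r.scope == "Fe"][0].rho == pytest.approx(-1.0)

    def test_missing_pairs_dropped(self):
        table = _replicate_table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, np.nan])
        res = replicate_precision(table)
        assert res[0].n_pairs == 3

    def test_single_replicate_rejected(self):
        table = _replicate_table([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            replicate_precision(table[table.replicate == 1])


class TestSummary:
    def _result(self, p, factor="state", scope="overall", taxon="fish"):
        return ComparisonResult(factor=factor, comparison="thawed vs dried", scope=scope,
                                estimate=1.0, statistic=1.0, p_value=p, taxon=taxon)

    def test_alpha_boundary_is_strict(self):
        matrix = summarize_study([self._result(0.05)], alpha=0.05)
        assert matrix.loc[0, "state"] == "ns"
        matrix = summarize_study([self._result(0.049)], alpha=0.05)
        assert matrix.loc[0, "state"] == "significant"

    def test_empty_per_element_cells_blank(self):
        matrix = summarize_study([self._result(0.01)], alpha=0.05)
        assert matrix.loc[0, "state_n_sig_elements"] == 0
        assert matrix.loc[0, "scan_time"] == ""

    def test_precision_column(self):
        matrix = summarize_study(
            [self._result(0.01)],
            precision=[PrecisionResult("overall", 0.9987, 100)],
        )
        assert matrix.loc[0, "replicate_spearman"] == 0.999

    def test_nothing_to_summarise_rejected(self):
        with pytest.raises(ValueError):
            summarize_study([])


def test_bh_adjustment_monotone(rng):
    p = rng.uniform(size=20)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
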