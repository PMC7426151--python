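"""TD statistics, categories, enrichment machinery, resampling nulls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dupli_td.errors import InputError
from dupli_td.td import (
    CATEGORIES,
    binomial_td_enrichment,
    category_count_null,
    classify_pair_category,
    classify_tdc,
    compare_groups_ranksum,
    compute_td,
    fisher_enrichment,
    overlap_summary,
    plasticity_td_correlation,
    resampling_null_mean,
    td_table,
    td_threshold_sweep,
)


class TestComputeTd:
    def test_boundary_is_strict(self):
        ratio, is_td = compute_td(100, 80)
        assert ratio == pytest.approx(1.25) and not is_td

    def test_twofold_divergence(self):
        ratio, is_td = compute_td(100, 50)
        assert ratio == 2.0 and is_td

    def test_symmetry_under_copy_swap(self):
        assert compute_td(100, 50) == compute_td(50, 100)

    def test_double_zero_undefined(self):
        ratio, is_td = compute_td(0, 0)
        assert math.isnan(ratio) and not is_td

    def test_invalid_tau(self):
        with pytest.raises(InputError):
            compute_td(2, 1, tau=0.5)


def pair_frame(means):
    rows = []
    for i, (a, b) in enumerate(means):
        rows.append({"pair_id": f"p{i}", "class": "WGD",
                     "gene_a": f"p{i}a", "gene_b": f"p{i}b",
                     "mean_a": a, "mean_b": b})
    return pd.DataFrame(rows)


class TestTdTable:
    def test_swap_invariance(self):
        expr = pair_frame([(100, 50), (80, 100), (30, 30)])
        swapped = expr.rename(columns={"mean_a": "mean_b", "mean_b": "mean_a",
                                       "gene_a": "gene_b", "gene_b": "gene_a"})
        t1, t2 = td_table(expr), td_table(swapped)
        assert np.allclose(t1["td_ratio"], t2["td_ratio"])
        assert (t1["is_td"] == t2["is_td"]).all()
        untied = t1["mean_a"] != t1["mean_b"]
        assert (t1.loc[untied, "high_copy"] == t2.loc[untied, "high_copy"]).all()
        # high/low copy undefined when the copy means tie
        assert t1.loc[~untied, "high_copy"].isna().all()
        assert t2.loc[~untied, "high_copy"].isna().all()

    def test_tdc_labels(self):
        expr = pair_frame([(100, 50)])
        row = td_table(expr).iloc[0]
        labels = classify_tdc(row, {"p0a": "up", "p0b": "unchanged"})
        assert labels == [("p0a", "up", "high-TDC")]
        labels = classify_tdc(row, {"p0a": "unchanged", "p0b": "down"})
        assert labels == [("p0b", "down", "low-TDC")]
        assert classify_tdc(row, {"p0a": "unchanged", "p0b": "unchanged"}) == []

    def test_tdc_refused_for_non_td_pair(self):
        row = td_table(pair_frame([(100, 90)])).iloc[0]
        with pytest.raises(InputError):
            classify_tdc(row, {"p0a": "up", "p0b": "up"})


class TestPairCategories:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("up", "up", "BothUp"),
            ("down", "down", "BothDown"),
            ("up", "down", "Discordant"),
            ("down", "up", "Discordant"),
            ("up", "unchanged", "OneUpOneUnchanged"),
            ("unchanged", "up", "OneUpOneUnchanged"),
            ("down", "unchanged", "OneDownOneUnchanged"),
            ("unchanged", "down", "OneDownOneUnchanged"),
            ("unchanged", "unchanged", "BothUnchanged"),
        ],
    )
    def test_total_symmetric_mapping(self, a, b, expected):
        assert classify_pair_category(a, b) == expected

    def test_unknown_call_rejected(self):
        with pytest.raises(InputError):
            classify_pair_category("up", "sideways")


def fisher_oracle(table):
    """Exhaustive fixed-margin two-sided Fisher p."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_no_association(self):
        res = fisher_enrichment([[10, 10], [10, 10]])
        assert res.odds_ratio == 1.0 and res.p == 1.0

    def test_perfect_separation_hand_value(self):
        res = fisher_enrichment([[5, 0], [0, 5]])
        assert res.p == pytest.approx(2 / math.comb(10, 5), abs=1e-12)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 13, size=(2, 2))
            assert fisher_enrichment(t).p == pytest.approx(fisher_oracle(t), abs=1e-12)

    def test_haldane_odds_ratio_with_zero_cell(self):
        res = fisher_enrichment([[5, 0], [2, 3]])
        assert res.odds_ratio == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))

    def test_negative_cell_rejected(self):
        with pytest.raises(InputError):
            fisher_enrichment([[1, -1], [0, 2]])


class TestBinomial:
    def test_all_successes_closed_form(self):
        assert binomial_td_enrichment(3, 3, 0.5).p == pytest.approx(0.125)

    def test_zero_successes_upper_tail_is_one(self):
        assert binomial_td_enrichment(0, 10, 0.3).p == pytest.approx(1.0)

    def test_invalid_p0_rejected(self):
        with pytest.raises(InputError):
            binomial_td_enrichment(1, 2, 1.0)

    def test_two_sided_matches_minlike_convention(self):
        k, n, p0 = 7, 20, 0.2
        pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
        expect = pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()
        assert binomial_td_enrichment(k, n, p0, "two-sided").p == pytest.approx(expect)


class TestResamplingNull:
    def test_degenerate_subset_is_whole_pool(self):
        null = resampling_null_mean(np.arange(5.0), 5, observed=2.0, n_iter=100, seed=0)
        assert null.p == 1.0
        assert np.allclose(null.null, 2.0)

    def test_small_pool_matches_exhaustive_enumeration(self):
        pool = np.array([1.0, 2.0, 3.0])
        null = resampling_null_mean(pool, 2, observed=2.5, n_iter=6000, seed=1,
                                    direction="greater")
        # exhaustive subsets {1,2},{1,3},{2,3}: means 1.5, 2, 2.5 -> p = 1/3
        se = math.sqrt((1 / 3) * (2 / 3) / 6000)
        assert abs(null.p - 1 / 3) <= 3 * se

    def test_seed_reproducibility(self):
        a = resampling_null_mean(np.arange(20.0), 5, observed=9.0, n_iter=500, seed=7)
        b = resampling_null_mean(np.arange(20.0), 5, observed=9.0, n_iter=500, seed=7)
        assert np.array_equal(a.null, b.null)

    def test_oversized_subset_rejected(self):
        with pytest.raises(InputError):
            resampling_null_mean(np.arange(3.0), 4, observed=1.0)

    def test_p_lower_bound_and_custom_statistic(self):
        pool = np.concatenate([np.zeros(30), [100.0]])
        null = resampling_null_mean(pool, 1, observed=100.0, n_iter=999, seed=2,
                                    statistic=np.median, direction="greater")
        assert null.p >= 1 / (999 + 1)


class TestCategoryNull:
    def test_all_unchanged(self):
        calls = ["unchanged"] * 30
        res = category_count_null(calls, calls, n_iter=200, seed=0)
        assert res.loc["BothUnchanged", "observed"] == 30
        assert res.loc["BothUnchanged", "p"] == 1.0

    def test_counts_conserved_in_null(self):
        rng = np.random.default_rng(1)
        calls = rng.choice(["up", "down", "unchanged"], size=(2, 80))
        res = category_count_null(calls[0], calls[1], n_iter=300, seed=3)
        assert res["observed"].sum() == 80
        assert res["null_mean"].sum() == pytest.approx(80)

    def test_planted_coordination_detected(self):
        # 50 pairs forced BothDown against an unchanged background
        calls_a = ["down"] * 50 + ["unchanged"] * 150
        calls_b = ["down"] * 50 + ["unchanged"] * 150
        res = category_count_null(calls_a, calls_b, n_iter=999, seed=4)
        assert res.loc["BothDown", "p"] <= 10 / (999 + 1)
        assert res.loc["BothDown", "direction"] == "greater"


class TestPlasticityCorrelation:
    def test_self_correlation(self):
        x = np.array([1.2, 1.5, 2.0, 3.0])
        r, _ = plasticity_td_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            plasticity_td_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_planted_log_linear_coupling(self):
        rng = np.random.default_rng(5)
        log_td = rng.uniform(0.1, 1.5, 200)
        log_plast = log_td + rng.normal(0, 0.1, 200)
        r, p = plasticity_td_correlation(np.exp(log_td), np.exp(log_plast))
        assert r >= 0.9 and p < 1e-10


class TestSweep:
    def make_inputs(self):
        rng = np.random.default_rng(6)
        means = []
        for _ in range(60):
            base = rng.lognormal(4, 0.5)
            means.append((base, base * rng.lognormal(0, 0.6)))
        means += [(50.0, 50.0)] * 10  # exact ties stay out of the tau=1 pool
        expr = pair_frame(means)
        calls = {}
        for i in range(70):
            calls[f"p{i}a"] = "up" if i % 3 == 0 else "unchanged"
            calls[f"p{i}b"] = "down" if i % 7 == 0 else "unchanged"
        return expr, calls

    def test_pool_monotone_in_tau(self):
        expr, calls = self.make_inputs()
        sweep = td_threshold_sweep(expr, calls, taus=[1.0, 1.25, 2.0, 3.0, 4.0])
        for (_, _), grp in sweep.groupby(["class", "direction"]):
            assert (np.diff(grp.sort_values("tau")["n_td_pairs"]) <= 0).all()

    def test_tau_one_saturates(self):
        expr, calls = self.make_inputs()
        sweep = td_threshold_sweep(expr, calls, taus=[1.0])
        row = sweep[(sweep["class"] == "all") & (sweep["direction"] == "up")].iloc[0]
        assert row["p0"] > 0.8
        assert row["undefined"] or row["p"] > 0.2

    def test_tau_above_max_ratio_flagged(self):
        expr, calls = self.make_inputs()
        big = float(np.nanmax(td_table(expr, 1.0)["td_ratio"])) + 1
        sweep = td_threshold_sweep(expr, calls, taus=[big])
        assert sweep["undefined"].all()

    def test_tau_below_one_rejected(self):
        expr, calls = self.make_inputs()
        with pytest.raises(InputError):
            td_threshold_sweep(expr, calls, taus=[0.9])


class TestRankSum:
    def test_identical_groups(self):
        p, ma, mb = compare_groups_ranksum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9 and ma == mb

    def test_exact_small_sample_value(self):
        p, _, _ = compare_groups_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        p, _, _ = compare_groups_ranksum(a, b)
        assert p < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            compare_groups_ranksum([], [1.0])


class TestOverlaps:
    def test_disjoint_sets(self):
        ov = overlap_summary({"A": {1, 2}, "B": {3, 4}})
        assert ov.percentage("A", "B") == 0.0 and ov.core_size == 0

    def test_core_is_triple_intersection(self):
        ov = overlap_summary({
            "t0": {1, 2, 3, 4}, "t100": {2, 3, 4, 5}, "t110": {3, 4, 6},
        })
        assert ov.core == {3, 4}
        assert ov.percentage("t0", "t100") == 75.0
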