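import numpy as np
import pandas as pd
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import exact_mann_whitney_p
from carepulse import stats


class TestPercentage:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (876_384, 2_759_257, 31.76),
            (13_885, 20_000, 69.43),   # 69.425 rounds half-up, not to even
            (0, 10, 0.00),
            (9_252_004, 27_309_724, 33.88),
            (-1, 8, -12.50),
        ],
    )
    def test_printed_ratios(self, num, den, expected):
        assert stats.percentage(num, den) == expected

    def test_half_away_from_zero_negative(self):
        assert stats.percentage(-13_885, 20_000) == -69.43

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            stats.percentage(1, 0)


class TestRates:
    @pytest.mark.parametrize(
        "pos,neg,pop,expected",
        [(46, 100, 100_000, -54.0), (7, 7, 12_345, 0.0), (10, 64, 200_000, -27.0)],
    )
    def test_polarity_rate(self, pos, neg, pop, expected):
        assert stats.polarity_rate(pos, neg, pop) == pytest.approx(expected)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_polarity_rate_antisymmetry(self, pos, neg):
        assert stats.polarity_rate(pos, neg, 50_000) == pytest.approx(
            -stats.polarity_rate(neg, pos, 50_000)
        )

    @pytest.mark.parametrize("n,pop,expected", [(372, 100_000, 372.0), (0, 5, 0.0),
                                                (239, 100_000, 239.0)])
    def test_tweet_rate(self, n, pop, expected):
        assert stats.tweet_rate(n, pop) == pytest.approx(expected)

    def test_rates_require_positive_population(self):
        with pytest.raises(ValueError):
            stats.polarity_rate(1, 1, 0)
        with pytest.raises(ValueError):
            stats.tweet_rate(1, -5)

    def test_region_rate_unweighted_mean(self):
        assert stats.region_polarity_rate([-10, -20]) == pytest.approx(-15.0)
        assert stats.region_polarity_rate([-42.0]) == pytest.approx(-42.0)

    def test_region_rate_population_weighted_flag(self):
        # two states, rates -10 and -20, populations 1M and 3M:
        # (-10*1 + -20*3) / 4 = -17.5
        assert stats.region_polarity_rate(
            [-10, -20], populations=[1_000_000, 3_000_000]
        ) == pytest.approx(-17.5)

    def test_region_rate_empty_error(self):
        with pytest.raises(ValueError):
            stats.region_polarity_rate([])


class TestQuantilePartition:
    def test_eight_distinct_scores_two_per_bin(self):
        bins = stats.quantile_partition([1, 2, 3, 4, 5, 6, 7, 8])
        assert [len(b) for b in bins] == [2, 2, 2, 2]

    def test_bin_means_nondecreasing_and_q1_most_negative(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-0.6, 0.1, 300), rng.normal(0.4, 0.2, 200)])
        bins = stats.quantile_partition(x)
        means = [x[b].mean() for b in bins]
        assert means == sorted(means)
        assert means[0] < means[-1]

    def test_conservation(self):
        x = np.random.default_rng(1).normal(size=101)
        bins = stats.quantile_partition(x)
        assert sum(len(b) for b in bins) == 101
        assert sorted(np.concatenate(bins)) == list(range(101))

    def test_boundary_ties_go_to_lower_bin(self):
        # scores [1,1,1,1,2,2,2,2]: quartiles are q1=1, q2=1.5, q3=2;
        # all four 1s fall in Q1 (<= q1), all four 2s in Q3 (<= q3)
        bins = stats.quantile_partition([1, 1, 1, 1, 2, 2, 2, 2])
        assert [len(b) for b in bins] == [4, 0, 4, 0]

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            stats.quantile_partition([1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(2 / 20)

    def test_interleaved_exact(self):
        u, p = stats.mann_whitney([1, 3], [2, 4])
        assert u == 1 and p == pytest.approx(4 / 6)

    def test_all_tied(self):
        u, p = stats.mann_whitney([5.0] * 10, [5.0] * 12)
        assert u == pytest.approx(10 * 12 / 2)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            stats.mann_whitney([], [1.0])

    def test_normal_approximation_close_to_enumeration_n5_to_8(self):
        """Tie-corrected normal approximation within 0.02 of brute force."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n1, n2 = rng.integers(5, 9, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1, n2)
            _, p_norm = stats.mann_whitney(a, b, exact_limit=0)
            _, p_exact = exact_mann_whitney_p(list(a), list(b))
            assert abs(p_norm - p_exact) <= 0.02


class TestCohensD:
    def test_identical_groups(self):
        assert stats.cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_hand_computed(self):
        # a=[0,2], b=[1,3]: means 1 vs 2, pooled SD sqrt(2) -> -1/sqrt(2)
        assert stats.cohens_d([0, 2], [1, 3]) == pytest.approx(-0.7071, abs=1e-4)

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1, 1, 20_000)
        b = rng.normal(0, 1, 20_000)
        assert stats.cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0.2, 1, 40), rng.normal(0, 1.3, 55)
        assert stats.cohens_d(a, b) == pytest.approx(
            pingouin.compute_effsize(a, b, eftype="cohen"), abs=1e-9
        )

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            stats.cohens_d([1], [2, 3])
        with pytest.raises(ValueError):
            stats.cohens_d([1, 1], [1, 1])


def _toy_table(n=800, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    states = rng.choice(["WA", "CA", "IL", "OH", "TX", "GA", "NY", "MA", "DC"], n)
    metro = rng.random(n) < 0.6
    score = np.where(
        rng.random(n) < 0.5, rng.normal(-0.5, 0.2, n), rng.normal(0.45, 0.2, n)
    )
    score = score + np.where(metro, shift, 0.0)
    score[:5] = 0.0  # a few zero-score posts that must be excluded
    return pd.DataFrame({"score": score, "state": states, "metro": metro})


class TestCompareTable:
    def test_row_structure_and_conservation(self):
        table = stats.compare_table(_toy_table())
        assert len(table) == 25
        assert set(table["quantile"]) == set(stats.QUANTILES)
        nat = table[table["scope"] == stats.NATIONAL]
        all_row = nat[nat["quantile"] == "ALL"].iloc[0]
        q_sum = nat[nat["quantile"] != "ALL"][["n_metro", "n_nonmetro"]].sum().sum()
        assert all_row["n_metro"] + all_row["n_nonmetro"] == q_sum

    def test_dc_pr_and_zero_scores_excluded(self):
        df = _toy_table()
        table = stats.compare_table(df)
        nat = table[(table["scope"] == stats.NATIONAL) & (table["quantile"] == "ALL")].iloc[0]
        expected = ((df["state"] != "DC") & (df["score"] != 0.0)).sum()
        assert nat["n_metro"] + nat["n_nonmetro"] == expected

    def test_shift_detected_in_all_row(self):
        table = stats.compare_table(_toy_table(n=4000, shift=-0.2, seed=1))
        nat = table[(table["scope"] == stats.NATIONAL) & (table["quantile"] == "ALL")].iloc[0]
        assert nat["p_value"] < 0.001
        assert nat["cohens_d"] < 0
        assert pd.notna(nat["d_reported"])

    def test_d_reported_only_when_significant(self):
        table = stats.compare_table(_toy_table(n=400, shift=0.0, seed=2))
        for _, row in table.iterrows():
            if pd.notna(row["d_reported"]):
                assert row["p_value"] < 0.001

    def test_untestable_scope_marked(self):
        df = _toy_table(n=200)
        df = df[~((df["state"].map(
            {"NY": "NORTHEAST", "MA": "NORTHEAST"}).eq("NORTHEAST")) & df["metro"])]
        table = stats.compare_table(df)
        ne_all = table[(table["scope"] == "NORTHEAST") & (table["quantile"] == "ALL")].iloc[0]
        assert not ne_all["testable"] and pd.isna(ne_all["p_value"])
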