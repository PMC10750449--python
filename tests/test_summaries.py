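import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hale_ensemble as he
from hale_ensemble.ensemble import ProjectionSummary
from hale_ensemble.summaries import Cell, GapRecord, count_gap_directions, round1


def summary_from(values: dict) -> ProjectionSummary:
    rows = [(a, y, v, v - 1.0, v + 1.0) for (a, y), v in values.items()]
    return ProjectionSummary(
        table=pd.DataFrame(rows, columns=["age", "year", "median", "cri_low", "cri_high"])
    )


class TestRounding:
    @pytest.mark.parametrize("x,expected", [(65.25, 65.3), (2.55, 2.6),
                                            (-1.04, -1.0), (40.65, 40.7)])
    def test_round_half_up_one_decimal(self, x, expected):
        assert round1(x) == expected


class TestChangeAndGaps:
    def test_change_between_years(self):
        a = Cell(value=62.7, sex="male", age=0.0, year=2020)
        b = Cell(value=65.3, sex="male", age=0.0, year=2030)
        assert he.change_between(a, b) == 2.6

    def test_identity_and_sign_convention(self):
        assert he.change_between(10.0, 10.0) == 0.0
        assert he.change_between(10.0, 9.0) == -1.0

    def test_mismatched_strata_rejected(self):
        a = Cell(value=62.7, sex="male", age=0.0)
        b = Cell(value=65.1, sex="female", age=0.0)
        with pytest.raises(ValueError, match="sex"):
            he.change_between(a, b)

    def test_sex_gap_values(self):
        assert he.sex_gap(65.1, 62.7) == 2.4
        assert he.sex_gap(67.5, 65.3) == 2.2
        assert he.sex_gap(50.0, 50.0) == 0.0

    def test_sex_gap_operand_roles_enforced(self):
        with pytest.raises(ValueError, match="female"):
            he.sex_gap(Cell(value=62.7, sex="male"), Cell(value=65.1, sex="male"))

    def test_birth_minus_age_50(self):
        male_2020 = summary_from({(0.0, 2020): 62.7, (50.0, 2020): 22.0})
        female_2030 = summary_from({(0.0, 2030): 67.5, (50.0, 2030): 25.2})
        assert he.birth_minus_age(male_2020, 2020) == 40.7
        assert he.birth_minus_age(female_2030, 2030) == 42.3
        same = summary_from({(0.0, 2020): 30.0, (50.0, 2020): 30.0})
        assert he.birth_minus_age(same, 2020) == 0.0

    def test_missing_age_row_rejected(self):
        with pytest.raises(KeyError):
            he.birth_minus_age(summary_from({(0.0, 2020): 62.7}), 2020)

    def test_draw_level_change_median_within_cri(self):
        rng = np.random.default_rng(0)
        a = 62.0 + rng.normal(0, 1, 1000)
        b = 65.0 + rng.normal(0, 1, 1000)
        diff = he.change_draws(a, b)
        lo, hi = np.percentile(diff, [2.5, 97.5])
        assert lo <= np.median(diff) <= hi


class TestExceedance:
    def test_trivial_cases(self):
        assert he.exceedance_probability(np.full(10, 80.0), 75.2) == 1.0
        assert he.exceedance_probability([70, 76, 77, 74], 75.2) == 0.5
        assert he.exceedance_probability([70, 71], 99.0) == 0.0

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50),
           st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_in_threshold(self, draws, t1, t2):
        lo, hi = sorted((t1, t2))
        p_lo = he.exceedance_probability(draws, lo)
        p_hi = he.exceedance_probability(draws, hi)
        assert 0.0 <= p_hi <= p_lo <= 1.0


class TestRankProbabilities:
    def test_separated_countries_get_certain_ranks(self):
        table = he.rank_probabilities({"A": [75, 76, 77], "B": [60, 61, 62]})
        assert table.rank_probability("A", 1) == 1.0
        assert table.rank_probability("B", 2) == 1.0

    def test_matches_brute_force_enumeration(self):
        draws = {"A": [70.0, 72.0, 68.0, 71.0],
                 "B": [71.0, 69.0, 69.5, 73.0],
                 "C": [69.0, 71.0, 70.0, 72.0]}
        table = he.rank_probabilities(draws)
        countries = sorted(draws)
        counts = {c: [0, 0, 0] for c in countries}
        for sim in range(4):
            ranked = sorted(countries, key=lambda c: (-draws[c][sim], c))
            for r, c in enumerate(ranked):
                counts[c][r] += 1
        for c in countries:
            for r in range(3):
                assert table.rank_probability(c, r + 1) == counts[c][r] / 4

    def test_tie_break_is_deterministic_and_flagged(self):
        table = he.rank_probabilities({"A": [70.0], "B": [70.0]})
        assert table.ties_broken
        assert table.rank_probability("A", 1) == 1.0  # identifier order

    def test_top_k_membership(self):
        table = he.rank_probabilities({"A": [75, 60], "B": [70, 70], "C": [65, 80]})
        assert table.top_k_probability("C", 2) == 0.5

    @given(st.integers(2, 6), st.integers(1, 30), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_rank_matrix_is_doubly_stochastic(self, n_countries, n_draws, seed):
        rng = np.random.default_rng(seed)
        draws = {f"C{i}": rng.normal(60, 5, n_draws) for i in range(n_countries)}
        table = he.rank_probabilities(draws)
        assert np.allclose(table.probabilities.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(table.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_unequal_draw_counts_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            he.rank_probabilities({"A": [70, 71], "B": [70.0]})


class TestRangeGap:
    def test_highest_vs_lowest_country_gap_change(self):
        male = he.range_gap_change({"Lesotho": 42.6, "Singapore": 74.1},
                                   {"Lesotho": 40.4, "Singapore": 77.4})
        female = he.range_gap_change({"Lesotho": 46.7, "Singapore": 75.6},
                                     {"Lesotho": 44.1, "Singapore": 78.2})
        assert male == 5.5
        assert female == 5.2

    def test_identical_medians_give_zero(self):
        m = {"A": 60.0, "B": 70.0}
        assert he.range_gap_change(m, m) == 0.0

    def test_fewer_than_two_countries_rejected(self):
        with pytest.raises(ValueError):
            he.range_gap_change({"A": 60.0}, {"A": 61.0})


def test_gap_direction_counting():
    records = [
        GapRecord("A", gap_a=2.4, gap_b=2.2),  # shrinking female advantage
        GapRecord("B", gap_a=1.0, gap_b=1.5),  # widening
        GapRecord("C", gap_a=-0.5, gap_b=-0.5),
        GapRecord("D", gap_a=3.0, gap_b=2.0),
    ]
    assert count_gap_directions(records) == (2, 1, 1)
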