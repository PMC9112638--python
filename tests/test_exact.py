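"""Exact-test machinery against hand computations and independent oracles."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from scipy import stats as scipy_stats

from polypsurv.exact import (
    Alternative,
    ContingencyTable,
    EnumerationLimitError,
    enumerate_tables,
    fisher_2x2,
    freeman_halton,
    table_probability,
)


def T(*rows):
    return ContingencyTable.from_counts(rows)


# --- independent oracle: brute force over all r x 2 matrices, factorial form ---

def oracle_mass(cells, row_totals, col_totals):
    n = sum(row_totals)
    num = 1
    for r in row_totals:
        num *= factorial(r)
    for c in col_totals:
        num *= factorial(c)
    den = factorial(n)
    for a, b in cells:
        den *= factorial(a) * factorial(b)
    return Fraction(num, den)


def oracle_all_tables(row_totals, col1):
    for left in itertools.product(*[range(r + 1) for r in row_totals]):
        if sum(left) == col1:
            yield tuple((a, r - a) for a, r in zip(left, row_totals))


def oracle_freeman_halton(counts):
    row_totals = [a + b for a, b in counts]
    col_totals = [sum(a for a, _ in counts), sum(b for _, b in counts)]
    if 0 in col_totals:
        return Fraction(1)
    p_obs = oracle_mass(counts, row_totals, col_totals)
    return sum(
        p
        for cells in oracle_all_tables(row_totals, col_totals[0])
        if (p := oracle_mass(cells, row_totals, col_totals)) <= p_obs
    )


class TestTableProbability:
    def test_hand_computed_mass(self):
        # C(13,6) C(6,3) / C(19,9) = 10080/27132
        assert table_probability(T([6, 7], [3, 3])) == pytest.approx(
            10080 / 27132, rel=1e-12
        )

    def test_diagonal_table(self):
        assert table_probability(T([5, 0], [0, 5])) == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_column_is_unique_table(self):
        assert table_probability(T([4, 0], [7, 0])) == 1.0


class TestEnumeration:
    def test_support_sizes(self):
        assert len(list(enumerate_tables([13, 6], [9, 10]))) == 7  # k = 3..9
        assert len(list(enumerate_tables([5, 5], [5, 5]))) == 6  # k = 0..5

    def test_mass_normalizes(self):
        row_totals, col_totals = [4, 7, 5], [6, 10]
        total = sum(
            oracle_mass(cells, row_totals, col_totals)
            for cells in enumerate_tables(row_totals, col_totals)
        )
        assert total == 1

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_tables([3, 3], [2, 2]))

    def test_cap_raises_rather_than_approximating(self):
        with pytest.raises(EnumerationLimitError):
            list(enumerate_tables([10, 10, 10], [15, 15], max_tables=5))


class TestFisher2x2:
    def test_published_gender_comparison_seven_scenarios(self):
        assert fisher_2x2(T([6, 7], [3, 3])) == pytest.approx(0.63, abs=0.005)
        assert fisher_2x2(T([6, 7], [3, 3])) == pytest.approx(17094 / 27132, rel=1e-12)

    def test_published_gender_comparison_twelve_scenarios(self):
        assert fisher_2x2(T([3, 2], [2, 3])) == pytest.approx(126 / 252, rel=1e-12)

    def test_two_sided_sums_all_tables_at_modal_observation(self):
        assert fisher_2x2(T([3, 2], [2, 3]), Alternative.TWO_SIDED) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_zero_total_rows_dropped_before_testing(self):
        with_na = ContingencyTable((("A", 6, 7), ("NA_GROUP", 0, 0), ("B", 3, 3)))
        assert fisher_2x2(with_na) == fisher_2x2(T([6, 7], [3, 3]))

    def test_more_than_two_rows_is_contract_violation(self):
        with pytest.raises(ValueError):
            fisher_2x2(T([1, 1], [1, 1], [1, 1]))

    def test_agrees_with_scipy_two_sided(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = rng.integers(0, 8, size=(2, 2))
            if counts.sum() == 0 or 0 in counts.sum(axis=0) or 0 in counts.sum(axis=1):
                continue
            ours = fisher_2x2(T(*counts.tolist()), Alternative.TWO_SIDED)
            theirs = scipy_stats.fisher_exact(counts).pvalue
            assert ours == pytest.approx(theirs, rel=1e-9)


class TestFreemanHalton:
    def test_published_clinician_type_seven_scenarios(self):
        # surgeons 2/5, gastroenterologists 2/4, PCPs 3/4, residents 3/6
        p = freeman_halton(T([2, 3], [2, 2], [3, 1], [3, 3]))
        assert p == pytest.approx(0.86, abs=0.005)

    def test_published_clinician_type_twelve_scenarios(self):
        # modal observed table: every table is at most as probable, p = 1
        assert freeman_halton(T([2, 2], [2, 2], [1, 1])) == pytest.approx(1.0, rel=1e-12)
        assert freeman_halton(T([2, 2], [2, 2], [1, 1])) > 0.99

    def test_reduces_to_two_sided_fisher_on_two_rows(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            counts = rng.integers(0, 9, size=(2, 2)).tolist()
            try:
                table = T(*counts).informative()
            except ValueError:
                continue
            if len(table.rows) != 2:
                continue
            assert freeman_halton(table) == pytest.approx(
                fisher_2x2(table, Alternative.TWO_SIDED), rel=1e-12
            )

    def test_agrees_with_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 60:
            r = int(rng.integers(2, 5))
            counts = rng.integers(0, 6, size=(r, 2))
            if counts.sum() > 30 or any(counts.sum(axis=1) == 0):
                continue
            counts = counts.tolist()
            ours = freeman_halton(T(*counts))
            exact = oracle_freeman_halton([tuple(c) for c in counts])
            assert ours == pytest.approx(float(exact), rel=1e-12)
            checked += 1

    def test_row_permutation_invariance(self):
        rows = [[2, 3], [4, 1], [0, 5]]
        base = freeman_halton(T(*rows))
        for perm in itertools.permutations(rows):
            assert freeman_halton(T(*perm)) == pytest.approx(base, rel=1e-12)


class TestInvariants:
    @pytest.mark.parametrize(
        "counts", [[[6, 7], [3, 3]], [[1, 5], [4, 2]], [[5, 0], [0, 5]], [[2, 2], [3, 3]]]
    )
    def test_p_in_unit_interval_and_two_sided_dominates_min_tail(self, counts):
        table = T(*counts)
        one = fisher_2x2(table, Alternative.ONE_SIDED_MIN_TAIL)
        two = fisher_2x2(table, Alternative.TWO_SIDED)
        assert 0 < one <= 1 and 0 < two <= 1
        assert two >= one - 1e-12

    def test_column_swap_invariance_two_sided(self):
        a = fisher_2x2(T([6, 7], [3, 3]), Alternative.TWO_SIDED)
        b = fisher_2x2(T([7, 6], [3, 3]), Alternative.TWO_SIDED)
        assert a == pytest.approx(b, rel=1e-12)
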