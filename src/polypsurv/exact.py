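"""Exact inference on small r x 2 contingency tables.

Implements the conditional (fixed-margins) machinery behind Fisher's exact
test and its Freeman–Halton extension to more than two rows, by complete
enumeration of the tables consistent with the observed margins.  Table
probabilities are multivariate-hypergeometric masses computed in exact
rational arithmetic (:class:`fractions.Fraction`); floats appear only at the
API boundary, so tie detection in the two-sided sum never depends on
floating-point rounding.

Sidedness conventions
---------------------
``ONE_SIDED_MIN_TAIL`` (default for 2x2 audit reports) is the smaller of the
lower- and upper-tail probabilities of the top-left cell, inclusive of the
observed table — the tail in the direction of the observed deviation.
``TWO_SIDED`` sums the probability of every margin-consistent table whose
probability does not exceed the observed one (the convention of R's
``fisher.test``); on two rows the Freeman–Halton test reduces to it exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterator, Sequence

#: Relative tolerance for "probability <= observed" ties in two-sided sums.
TIE_RTOL = Fraction(1, 10**12)

#: Default cap on the number of enumerated tables before raising.
DEFAULT_MAX_TABLES = 2_000_000


class Alternative(str, enum.Enum):
    ONE_SIDED_MIN_TAIL = "ONE_SIDED_MIN_TAIL"
    TWO_SIDED = "TWO_SIDED"


class EnumerationLimitError(RuntimeError):
    """The enumeration would exceed the configured table cap."""


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 table of (label, low_count, high_count) rows."""

    rows: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if any(low < 0 or high < 0 for _, low, high in self.rows):
            raise ValueError("counts must be non-negative")
        informative = [r for r in self.rows if r[1] + r[2] > 0]
        if len(informative) < 2:
            raise ValueError("need >= 2 rows with non-zero total")
        if sum(low + high for _, low, high in self.rows) < 1:
            raise ValueError("grand total must be >= 1")

    @classmethod
    def from_counts(
        cls, counts: Sequence[Sequence[int]], labels: Sequence[str] | None = None
    ) -> "ContingencyTable":
        labels = labels or [f"row{i}" for i in range(len(counts))]
        return cls(tuple((str(l), int(a), int(b)) for l, (a, b) in zip(labels, counts)))

    def informative(self) -> "ContingencyTable":
        """Drop rows with zero total (e.g. groups not given a battery)."""
        kept = tuple(r for r in self.rows if r[1] + r[2] > 0)
        return ContingencyTable(kept)

    @property
    def counts(self) -> tuple[tuple[int, int], ...]:
        return tuple((low, high) for _, low, high in self.rows)

    @property
    def row_totals(self) -> tuple[int, ...]:
        return tuple(low + high for _, low, high in self.rows)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (
            sum(low for _, low, _ in self.rows),
            sum(high for _, _, high in self.rows),
        )


def _mass(cells: Sequence[tuple[int, int]], col1_total: int, grand: int) -> Fraction:
    """Multivariate hypergeometric mass of one r x 2 table given its margins."""
    num = 1
    for a, b in cells:
        num *= comb(a + b, a)
    return Fraction(num, comb(grand, col1_total))


def table_probability(table: ContingencyTable) -> float:
    """Conditional probability of the observed table given its margins."""
    t = table.informative()
    return float(table_probability_exact(t))


def table_probability_exact(table: ContingencyTable) -> Fraction:
    t = table.informative()
    c1, c2 = t.col_totals
    if c1 == 0 or c2 == 0:
        return Fraction(1)  # the observed table is the only one with these margins
    return _mass(t.counts, c1, c1 + c2)


def enumerate_tables(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    max_tables: int = DEFAULT_MAX_TABLES,
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield every non-negative integer r x 2 table with the given margins.

    Raises :class:`EnumerationLimitError` once more than ``max_tables`` tables
    have been produced, and ValueError on inconsistent margins.
    """
    if len(col_totals) != 2:
        raise ValueError("enumerate_tables handles r x 2 tables")
    if any(r < 0 for r in row_totals) or any(c < 0 for c in col_totals):
        raise ValueError("margins must be non-negative")
    if sum(row_totals) != sum(col_totals):
        raise ValueError("row and column margins disagree on the grand total")

    n_rows = len(row_totals)
    produced = 0

    def rec(i: int, col1_left: int, acc: list[tuple[int, int]]) -> Iterator[
        tuple[tuple[int, int], ...]
    ]:
        nonlocal produced
        if i == n_rows:
            if col1_left == 0:
                produced += 1
                if produced > max_tables:
                    raise EnumerationLimitError(
                        f"enumeration exceeds the cap of {max_tables} tables"
                    )
                yield tuple(acc)
            return
        remaining_rows = sum(row_totals[i + 1 :])
        lo = max(0, col1_left - remaining_rows)
        hi = min(row_totals[i], col1_left)
        for a in range(lo, hi + 1):
            acc.append((a, row_totals[i] - a))
            yield from rec(i + 1, col1_left - a, acc)
            acc.pop()

    yield from rec(0, col_totals[0], [])


def fisher_2x2(table: ContingencyTable, alternative: Alternative | str = Alternative.ONE_SIDED_MIN_TAIL) -> float:
    """Fisher's exact test on a 2 x 2 table (after dropping zero-total rows)."""
    alternative = Alternative(alternative)
    t = table.informative()
    if len(t.rows) != 2:
        raise ValueError(f"fisher_2x2 needs exactly 2 informative rows, got {len(t.rows)}")
    (r1, r2) = t.row_totals
    c1, _ = t.col_totals
    grand = r1 + r2
    if c1 == 0 or c1 == grand:
        return 1.0
    a_obs = t.counts[0][0]
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    masses = {
        a: _mass(((a, r1 - a), (c1 - a, r2 - (c1 - a))), c1, grand)
        for a in range(lo, hi + 1)
    }
    if alternative is Alternative.ONE_SIDED_MIN_TAIL:
        lower = sum(p for a, p in masses.items() if a <= a_obs)
        upper = sum(p for a, p in masses.items() if a >= a_obs)
        return float(min(lower, upper))
    p_obs = masses[a_obs]
    threshold = p_obs * (1 + TIE_RTOL)
    return float(min(Fraction(1), sum(p for p in masses.values() if p <= threshold)))


def freeman_halton(table: ContingencyTable, max_tables: int = DEFAULT_MAX_TABLES) -> float:
    """Freeman–Halton exact test on an r x 2 table by complete enumeration.

    p = total mass of margin-consistent tables no more probable than the
    observed one (inclusive; ties detected with relative tolerance 1e-12 in
    exact arithmetic).  On 2 informative rows this equals
    ``fisher_2x2(..., TWO_SIDED)`` by construction.
    """
    t = table.informative()
    c1, c2 = t.col_totals
    if c1 == 0 or c2 == 0:
        return 1.0
    grand = c1 + c2
    p_obs = _mass(t.counts, c1, grand)
    threshold = p_obs * (1 + TIE_RTOL)
    total = Fraction(0)
    for cells in enumerate_tables(t.row_totals, t.col_totals, max_tables=max_tables):
        p = _mass(cells, c1, grand)
        if p <= threshold:
            total += p
    return float(min(Fraction(1), total))
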