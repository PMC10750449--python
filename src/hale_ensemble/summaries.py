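"""Derived quantities reported from pooled projections.

Covers changes between years, female-minus-male gaps, the birth-vs-age-50
difference, exceedance probabilities, cross-country range-gap changes, and
country rank probability tables.  Headline numbers are rounded half-up to
one decimal, the convention used when presenting HLE in years.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import ProjectionSummary

__all__ = [
    "Cell",
    "RankTable",
    "GapRecord",
    "round1",
    "change_between",
    "change_draws",
    "sex_gap",
    "birth_minus_age",
    "exceedance_probability",
    "rank_probabilities",
    "range_gap_change",
    "count_gap_directions",
]


def round1(x: float) -> float:
    """Round half-up to one decimal (65.25 -> 65.3), matching presentation."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Cell:
    """One summary value with the stratum labels needed for safe arithmetic."""

    value: float
    country: str | None = None
    sex: str | None = None
    age: float | None = None
    year: int | None = None


def _require_match(a: Cell, b: Cell, fields: Sequence[str]) -> None:
    for f in fields:
        va, vb = getattr(a, f), getattr(b, f)
        if va is not None and vb is not None and va != vb:
            raise ValueError(f"mismatched strata: {f} differs ({va!r} vs {vb!r})")


def change_between(cell_a: Cell | float, cell_b: Cell | float) -> float:
    """Difference of medians (b - a), rounded to one decimal."""
    a = cell_a if isinstance(cell_a, Cell) else Cell(value=float(cell_a))
    b = cell_b if isinstance(cell_b, Cell) else Cell(value=float(cell_b))
    _require_match(a, b, ("country", "sex", "age"))
    return round1(b.value - a.value)


def change_draws(draws_a: np.ndarray, draws_b: np.ndarray) -> np.ndarray:
    """Full posterior of the change: element-wise (b - a) over aligned draws."""
    a, b = np.asarray(draws_a, float), np.asarray(draws_b, float)
    if a.shape != b.shape:
        raise ValueError("draw arrays must be index-aligned with equal shapes")
    return b - a


def sex_gap(female: Cell | float, male: Cell | float) -> float:
    """Female-minus-male HLE gap in years, one decimal."""
    f = female if isinstance(female, Cell) else Cell(value=float(female), sex="female")
    m = male if isinstance(male, Cell) else Cell(value=float(male), sex="male")
    if (f.sex or "female") != "female" or (m.sex or "male") != "male":
        raise ValueError("sex_gap expects (female, male) operands in that order")
    _require_match(f, m, ("country", "age", "year"))
    return round1(f.value - m.value)


def birth_minus_age(summary: ProjectionSummary, year: int, age: float = 50.0) -> float:
    """HLE(0) - HLE(age) on medians for one stratum-year, one decimal."""
    return round1(summary.median(0.0, year) - summary.median(age, year))


def exceedance_probability(draws: np.ndarray, threshold: float) -> float:
    """Fraction of draws strictly greater than ``threshold``."""
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("at least one draw is required")
    return float(np.mean(d > threshold))


@dataclass
class RankTable:
    """Country-by-rank probability matrix (rank 1 = highest HLE).

    Each pooled simulation induces a full permutation of the countries, so
    rows and columns each sum to one.  ``ties_broken`` flags whether any
    simulation needed the deterministic country-identifier tie-break.
    """

    countries: list[str]
    probabilities: np.ndarray  # (n_countries, n_countries)
    n_draws: int
    ties_broken: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, r + 1, float(self.probabilities[i, r]))
            for i, c in enumerate(self.countries)
            for r in range(len(self.countries))
        ]
        return pd.DataFrame(rows, columns=["country", "rank", "probability"])

    def rank_probability(self, country: str, rank: int) -> float:
        return float(self.probabilities[self.countries.index(country), rank - 1])

    def top_k_probability(self, country: str, k: int) -> float:
        """Probability of being among the k highest-HLE countries."""
        return float(self.probabilities[self.countries.index(country), :k].sum())


def rank_probabilities(country_draws: Mapping[str, np.ndarray]) -> RankTable:
    """Rank countries within each simulation and tabulate rank frequencies.

    Draws must be index-aligned across countries (simulation i of country A
    pairs with simulation i of country B).  Ties are broken by country
    identifier order and flagged.
    """
    countries = sorted(country_draws)
    if len(countries) < 2:
        raise ValueError("at least two countries are required for ranking")
    arrs = [np.asarray(country_draws[c], dtype=float).ravel() for c in countries]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("all countries must supply the same number of draws")
    values = np.stack(arrs)  # (n_countries, n_sims)
    ties = bool((np.sort(values, axis=0)[:-1] == np.sort(values, axis=0)[1:]).any())
    # lexsort: primary key descending value, secondary key country order
    order = np.lexsort((np.arange(len(countries))[:, None].repeat(n, 1), -values), axis=0)
    counts = np.zeros((len(countries), len(countries)), dtype=float)
    for r in range(len(countries)):
        np.add.at(counts[:, r], order[r], 1.0)
    return RankTable(countries=countries, probabilities=counts / n,
                     n_draws=n, ties_broken=ties)


@dataclass(frozen=True)
class GapRecord:
    """Female-minus-male gap for one country in two reference years."""

    country: str
    gap_a: float
    gap_b: float
    sdi_group: str | None = None
    region: str | None = None


def range_gap_change(
    medians_a: Mapping[str, float], medians_b: Mapping[str, float]
) -> float:
    """Change in the cross-country (max - min) spread between two years."""
    if len(medians_a) < 2 or len(medians_b) < 2:
        raise ValueError("at least two countries are required in both years")
    spread_a = max(medians_a.values()) - min(medians_a.values())
    spread_b = max(medians_b.values()) - min(medians_b.values())
    return round1(spread_b - spread_a)


def count_gap_directions(records: Sequence[GapRecord]) -> tuple[int, int, int]:
    """(shrinking, widening, unchanged) counts of the female advantage."""
    shrink = sum(1 for r in records if r.gap_b < r.gap_a)
    widen = sum(1 for r in records if r.gap_b > r.gap_a)
    return shrink, widen, len(records) - shrink - widen
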