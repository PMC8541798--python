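"""Scale prevalences to user counts and aggregate into report tables.

The number of vapers in a country is prevalence x adult (15+) population.
Aggregation keeps counts as exact rationals internally so that group totals
conserve the world total *exactly* across every partition (income, region,
legal status, surveyed/estimated); rounding half-up to whole persons happens
only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Union

import pandas as pd

from .cascade import ImputedPrevalence
from .country_data import (
    FACTOR_NAMES,
    WorldTable,
    _FACTOR_ENUMS,
    round_half_up,
)

__all__ = ["EstimateRow", "vapers_count", "aggregate_estimates", "estimates_frame", "world_total"]

SURVEY_PARTITION = "survey_partition"
_SURVEYED_LABEL = "Countries with data from surveys"
_ESTIMATED_LABEL = "Countries with estimated data"


@dataclass(frozen=True)
class EstimateRow:
    """One report row: group label, number of countries, number of vapers.

    ``n_vapers`` is an exact rational; round at report time.
    """

    label: str
    n_countries: int
    n_vapers: Fraction

    @property
    def n_vapers_rounded(self) -> int:
        return int(round_half_up(float(self.n_vapers)))


def vapers_count(prevalence: float, adult_population: int) -> float:
    """Number of current users implied by a prevalence and an adult population."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    if adult_population < 0:
        raise ValueError(f"adult_population must be >= 0, got {adult_population}")
    return prevalence * adult_population


def _exact_count(prevalence: float, adult_population: int) -> Fraction:
    return Fraction(prevalence) * adult_population


def aggregate_estimates(
    result: dict[str, ImputedPrevalence],
    table: WorldTable,
    by: str = "world",
) -> list[EstimateRow]:
    """Aggregate per-country user counts into a partition of the world.

    ``by`` is ``"world"``, a factor name (rows per level, with an "Unknown"
    row collecting countries whose factor is unknown), or
    ``"survey_partition"`` (surveyed vs estimated countries). Rows partition
    the world: their exact ``n_vapers`` values sum to the world total.

    Raises
    ------
    KeyError
        If any country in the table lacks a value in ``result``.
    """
    if by != "world" and by != SURVEY_PARTITION and by not in FACTOR_NAMES:
        raise ValueError(
            f"unknown grouping {by!r}; expected 'world', {SURVEY_PARTITION!r} or one of {FACTOR_NAMES}"
        )

    missing = [r.iso3 for r in table.records if r.iso3 not in result]
    if missing:
        raise KeyError(f"no imputed/observed value for: {missing}")

    groups: dict[str, tuple[int, Fraction]] = {}
    for record in table.records:
        if by == "world":
            label = "World"
        elif by == SURVEY_PARTITION:
            label = _SURVEYED_LABEL if record.surveyed else _ESTIMATED_LABEL
        else:
            level = record.factors.get(by).value
            label = "Unknown" if level == "unknown" else level
        n, count = groups.get(label, (0, Fraction(0)))
        groups[label] = (
            n + 1,
            count + _exact_count(result[record.iso3].value, record.adult_population),
        )

    if by == "world":
        order = ["World"]
    elif by == SURVEY_PARTITION:
        order = [_SURVEYED_LABEL, _ESTIMATED_LABEL]
    else:
        order = [
            ("Unknown" if m.value == "unknown" else m.value) for m in _FACTOR_ENUMS[by]
        ]
    rows = [
        EstimateRow(label, *groups[label]) for label in order if label in groups
    ]
    return rows


def world_total(result: dict[str, ImputedPrevalence], table: WorldTable) -> Fraction:
    """Exact worldwide number of vapers."""
    rows = aggregate_estimates(result, table, by="world")
    return rows[0].n_vapers if rows else Fraction(0)


def estimates_frame(rows: list[EstimateRow]) -> pd.DataFrame:
    """Report rows as a DataFrame with counts rounded to whole persons."""
    return pd.DataFrame(
        {
            "group": [r.label for r in rows],
            "n_countries": [r.n_countries for r in rows],
            "n_vapers": [r.n_vapers_rounded for r in rows],
        }
    )
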