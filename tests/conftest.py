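"""Shared fixtures: hand-built toy worlds and a random-table generator."""

from __future__ import annotations

import numpy as np
import pytest
from statistics import fmean

from vapecast.cascade import DEFAULT_CASCADE
from vapecast.country_data import (
    CountryRecord,
    FactorValue,
    IncomeGroup,
    LegalStatus,
    SurveyObservation,
    WhoRegion,
    WorldTable,
)

REGIONS = [r for r in WhoRegion if r is not WhoRegion.UNKNOWN]
INCOMES = [g for g in IncomeGroup if g is not IncomeGroup.UNKNOWN]
LEGALS = [s for s in LegalStatus if s is not LegalStatus.UNKNOWN]


def make_record(
    iso3,
    region=WhoRegion.EUROPEAN,
    income=IncomeGroup.HIGH,
    legal=LegalStatus.ALLOWED,
    population=1_000_000,
    prevalence=None,
    year=2018,
    name=None,
):
    survey = None
    if prevalence is not None:
        survey = SurveyObservation(prevalence=prevalence, survey_year=year)
    return CountryRecord(
        iso3=iso3,
        name=name or f"Country {iso3}",
        factors=FactorValue(region, income, legal),
        adult_population=population,
        survey=survey,
    )


@pytest.fixture
def toy5():
    """Five countries exercising cascade levels 1, 2 and the global mean.

    A and B are surveyed high-income European allowed-sale countries at 2%
    and 4%; C shares their full subgroup, D shares only income and legal
    status, and E (low-income African, banned) shares nothing and must fall
    through to the global mean. All three unsurveyed countries should
    receive 3%.
    """
    return WorldTable(
        (
            make_record("AAA", prevalence=0.02),
            make_record("BBB", prevalence=0.04),
            make_record("CCC"),
            make_record("DDD", region=WhoRegion.AMERICAS),
            make_record(
                "EEE",
                region=WhoRegion.AFRICAN,
                income=IncomeGroup.LOW,
                legal=LegalStatus.BANNED,
            ),
        )
    )


def random_table(rng: np.random.Generator, n: int, p_survey=0.5, p_unknown=0.15) -> WorldTable:
    """A random world table, possibly with unknown factor levels."""
    records = []
    for i in range(n):
        iso3 = "".join(chr(ord("A") + int(c)) for c in rng.integers(0, 26, 3))
        iso3 = f"{chr(ord('A') + i % 26)}{iso3[1:]}"  # reduce collisions
        region = (
            WhoRegion.UNKNOWN
            if rng.random() < p_unknown
            else REGIONS[rng.integers(len(REGIONS))]
        )
        income = (
            IncomeGroup.UNKNOWN
            if rng.random() < p_unknown
            else INCOMES[rng.integers(len(INCOMES))]
        )
        legal = (
            LegalStatus.UNKNOWN
            if rng.random() < p_unknown
            else LEGALS[rng.integers(len(LEGALS))]
        )
        prevalence = float(rng.uniform(0.001, 0.08)) if rng.random() < p_survey else None
        records.append(
            make_record(
                iso3,
                region=region,
                income=income,
                legal=legal,
                population=int(rng.integers(10_000, 50_000_000)),
                prevalence=prevalence,
            )
        )
    try:
        return WorldTable(tuple(records))
    except ValueError:  # iso3 collision: resample
        return random_table(rng, n, p_survey, p_unknown)


def brute_force_impute(table: WorldTable, spec=DEFAULT_CASCADE):
    """Independent per-country reference: scan the cascade, recompute each
    candidate group mean from scratch by filtering the whole table."""
    out = {}
    for rec in table.records:
        if rec.surveyed:
            out[rec.iso3] = (rec.survey.prevalence, 0)
            continue
        for step, sig in enumerate(spec.signatures, start=1):
            if any(not rec.factors.is_known(f) for f in sig):
                continue
            values = [
                other.survey.prevalence
                for other in table.records
                if other.surveyed
                and all(other.factors.is_known(f) for f in sig)
                and all(other.factors.get(f) == rec.factors.get(f) for f in sig)
            ]
            if values:
                # same degenerate-case rule as the implementation: an
                # all-equal group means exactly that value
                mean = values[0] if min(values) == max(values) else fmean(values)
                out[rec.iso3] = (mean, step)
                break
    return out
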