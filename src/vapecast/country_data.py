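"""Data model and I/O for the country table and the market-revenue index.

The central container is a :class:`WorldTable`: one record per country or
territory carrying the three similarity factors (WHO region, World Bank
income classification, legal status of e-cigarette sale), the adult (15+)
population used as the prevalence denominator, and — where a qualifying
survey exists — an observed current-use vaping prevalence.

Unit convention: prevalence is a *fraction* in [0, 1] everywhere in memory;
all file and report I/O uses *percent*. Percentages in reports are rounded
half-up to two decimal places.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Mapping, Optional, Union

import pandas as pd

__all__ = [
    "WhoRegion",
    "IncomeGroup",
    "LegalStatus",
    "FactorValue",
    "SurveyObservation",
    "CountryRecord",
    "WorldTable",
    "MarketIndexSeries",
    "read_country_table",
    "write_country_table",
    "read_market_index",
    "write_market_index",
    "coverage_summary",
    "round_half_up",
    "FACTOR_NAMES",
]


class WhoRegion(str, enum.Enum):
    """The six WHO geographic regions, plus an explicit ``unknown`` level."""

    AFRICAN = "African"
    EASTERN_MEDITERRANEAN = "Eastern Mediterranean"
    EUROPEAN = "European"
    AMERICAS = "Americas"
    SOUTH_EAST_ASIA = "South-East Asia"
    WESTERN_PACIFIC = "Western Pacific"
    UNKNOWN = "unknown"


class IncomeGroup(str, enum.Enum):
    """World Bank income classification, plus an explicit ``unknown`` level."""

    HIGH = "high"
    UPPER_MIDDLE = "upper middle"
    LOWER_MIDDLE = "lower middle"
    LOW = "low"
    UNKNOWN = "unknown"


class LegalStatus(str, enum.Enum):
    """Legal status of e-cigarette sale, plus an explicit ``unknown`` level."""

    ALLOWED = "allowed"
    BANNED = "banned"
    NO_SPECIFIC_LAW = "no specific law"
    UNKNOWN = "unknown"


FACTOR_NAMES = ("who_region", "income_group", "legal_status")

_FACTOR_ENUMS = {
    "who_region": WhoRegion,
    "income_group": IncomeGroup,
    "legal_status": LegalStatus,
}

# Accepted spellings, lower-cased and lightly normalised. Blank cells map to
# the explicit "unknown" level: unknown is a first-class factor level, never
# an absent field.
_REGION_ALIASES = {
    "african": WhoRegion.AFRICAN,
    "afr": WhoRegion.AFRICAN,
    "eastern mediterranean": WhoRegion.EASTERN_MEDITERRANEAN,
    "emr": WhoRegion.EASTERN_MEDITERRANEAN,
    "european": WhoRegion.EUROPEAN,
    "eur": WhoRegion.EUROPEAN,
    "americas": WhoRegion.AMERICAS,
    "region of the americas": WhoRegion.AMERICAS,
    "amr": WhoRegion.AMERICAS,
    "south-east asia": WhoRegion.SOUTH_EAST_ASIA,
    "south east asia": WhoRegion.SOUTH_EAST_ASIA,
    "sear": WhoRegion.SOUTH_EAST_ASIA,
    "western pacific": WhoRegion.WESTERN_PACIFIC,
    "wpr": WhoRegion.WESTERN_PACIFIC,
    "unknown": WhoRegion.UNKNOWN,
}

_INCOME_ALIASES = {
    "high": IncomeGroup.HIGH,
    "upper middle": IncomeGroup.UPPER_MIDDLE,
    "lower middle": IncomeGroup.LOWER_MIDDLE,
    "low": IncomeGroup.LOW,
    "unknown": IncomeGroup.UNKNOWN,
}

_LEGAL_ALIASES = {
    "allowed": LegalStatus.ALLOWED,
    "banned": LegalStatus.BANNED,
    "no specific law": LegalStatus.NO_SPECIFIC_LAW,
    "unknown": LegalStatus.UNKNOWN,
}


def _parse_factor(raw: object, factor: str) -> enum.Enum:
    aliases: Mapping[str, enum.Enum] = {
        "who_region": _REGION_ALIASES,
        "income_group": _INCOME_ALIASES,
        "legal_status": _LEGAL_ALIASES,
    }[factor]
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return _FACTOR_ENUMS[factor].UNKNOWN
    text = str(raw).strip()
    if not text:
        return _FACTOR_ENUMS[factor].UNKNOWN
    norm = text.lower().replace("-income", "").replace("_", " ")
    norm = norm.replace("upper-middle", "upper middle").replace(
        "lower-middle", "lower middle"
    )
    if factor == "who_region":
        norm = norm.removesuffix(" region").strip()
        norm = norm.removeprefix("the ").strip()
    if factor == "income_group":
        norm = norm.removesuffix(" income").strip()
    if norm in aliases:
        return aliases[norm]
    accepted = sorted(set(aliases))
    raise ValueError(
        f"unrecognized {factor} label {text!r}; accepted labels: {accepted}"
    )


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FactorValue:
    """The three similarity factors of one country."""

    who_region: WhoRegion = WhoRegion.UNKNOWN
    income_group: IncomeGroup = IncomeGroup.UNKNOWN
    legal_status: LegalStatus = LegalStatus.UNKNOWN

    def get(self, factor: str) -> enum.Enum:
        if factor not in FACTOR_NAMES:
            raise KeyError(f"unknown factor {factor!r}; expected one of {FACTOR_NAMES}")
        return getattr(self, factor)

    def is_known(self, factor: str) -> bool:
        return self.get(factor).value != "unknown"


@dataclass(frozen=True)
class SurveyObservation:
    """One qualifying survey: current use (past 30 days) as a fraction."""

    prevalence: float
    survey_year: Optional[int] = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(
                f"prevalence must be a fraction in [0, 1], got {self.prevalence}"
            )


@dataclass(frozen=True)
class CountryRecord:
    """One country/territory; ``survey`` is None where no qualifying survey exists."""

    iso3: str
    name: str
    factors: FactorValue
    adult_population: int
    survey: Optional[SurveyObservation] = None

    def __post_init__(self) -> None:
        if len(self.iso3) != 3 or not self.iso3.isalpha():
            raise ValueError(f"iso3 must be a 3-letter code, got {self.iso3!r}")
        if self.adult_population < 0:
            raise ValueError(
                f"adult_population must be >= 0, got {self.adult_population} ({self.iso3})"
            )

    @property
    def surveyed(self) -> bool:
        return self.survey is not None


@dataclass
class WorldTable:
    """A collection of country records; iso3 codes are unique.

    Records are stored sorted by iso3, so tables built from row-permuted
    input compare equal.
    """

    records: tuple[CountryRecord, ...]
    reference_year: int = 2018

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.records, key=lambda r: r.iso3))
        seen: set[str] = set()
        for r in recs:
            if r.iso3 in seen:
                raise ValueError(f"duplicate iso3 code {r.iso3!r} in country table")
            seen.add(r.iso3)
        self.records = recs

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, iso3: str) -> CountryRecord:
        for r in self.records:
            if r.iso3 == iso3:
                return r
        raise KeyError(iso3)

    @property
    def surveyed(self) -> tuple[CountryRecord, ...]:
        return tuple(r for r in self.records if r.surveyed)

    @property
    def unsurveyed(self) -> tuple[CountryRecord, ...]:
        return tuple(r for r in self.records if not r.surveyed)

    def with_survey(self, iso3: str, survey: SurveyObservation) -> "WorldTable":
        """Return a copy in which ``iso3`` carries ``survey``."""
        recs = tuple(
            replace(r, survey=survey) if r.iso3 == iso3 else r for r in self.records
        )
        return WorldTable(recs, reference_year=self.reference_year)


@dataclass
class MarketIndexSeries:
    """Year-indexed market-revenue index in percent of a base year's revenue."""

    points: dict[int, float]
    base_year: int = 2018

    def __post_init__(self) -> None:
        for year, value in self.points.items():
            if not value > 0:
                raise ValueError(f"index value must be > 0, got {value} at {year}")
        self.points = dict(sorted(self.points.items()))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.points)

    def ratio(self, year: int, base_year: Optional[int] = None) -> float:
        """Index value at ``year`` relative to the base year (base -> 1.0)."""
        base = self.base_year if base_year is None else base_year
        if base not in self.points:
            raise KeyError(f"base year {base} not in series (years {self.years})")
        if year not in self.points:
            raise KeyError(f"year {year} not in series (years {self.years})")
        return self.points[year] / self.points[base]


# ---------------------------------------------------------------------------
# I/O

_DEFAULT_COLUMNS = {
    "iso3": "iso3",
    "name": "name",
    "who_region": "who_region",
    "income_group": "income_group",
    "legal_status": "legal_status",
    "adult_population": "adult_population",
    "prevalence_pct": "prevalence_pct",
    "survey_year": "survey_year",
    "source_label": "source_label",
}


def read_country_table(
    source: Union[str, IO[str]],
    schema_config: Optional[Mapping[str, str]] = None,
    survey_year_window: tuple[int, int] = (2012, 2020),
    reference_year: int = 2018,
) -> WorldTable:
    """Read a country table from delimited text.

    Parameters
    ----------
    source
        Path or open text stream of a CSV with a header row.
    schema_config
        Mapping from canonical column names (``iso3``, ``name``,
        ``who_region``, ``income_group``, ``legal_status``,
        ``adult_population``, ``prevalence_pct``, ``survey_year``,
        ``source_label``) to the file's column names.
    survey_year_window
        Inclusive range of acceptable survey years (survey inclusion
        criterion; default 2012-2020).
    reference_year
        Population reference year carried as table metadata.

    Notes
    -----
    Prevalence is given in *percent* in the file and stored as a fraction.
    A missing prevalence cell yields a record with no survey. Blank factor
    cells map to the explicit "unknown" level.
    """
    columns = dict(_DEFAULT_COLUMNS)
    if schema_config:
        columns.update(schema_config)
    df = pd.read_csv(source, dtype={columns["iso3"]: str})

    for required in ("iso3", "name", "who_region", "income_group", "legal_status", "adult_population"):
        if columns[required] not in df.columns:
            raise ValueError(f"missing required column {columns[required]!r}")

    records = []
    for _, row in df.iterrows():
        iso3 = str(row[columns["iso3"]]).strip().upper()
        factors = FactorValue(
            who_region=_parse_factor(row[columns["who_region"]], "who_region"),
            income_group=_parse_factor(row[columns["income_group"]], "income_group"),
            legal_status=_parse_factor(row[columns["legal_status"]], "legal_status"),
        )
        population = row[columns["adult_population"]]
        if pd.isna(population):
            raise ValueError(f"missing adult_population for {iso3}")
        population = int(population)

        survey = None
        pcol = columns["prevalence_pct"]
        if pcol in df.columns and not pd.isna(row[pcol]):
            pct = float(row[pcol])
            if not 0.0 <= pct <= 100.0:
                raise ValueError(
                    f"prevalence {pct}% for {iso3} outside [0, 100]%"
                )
            year = None
            ycol = columns["survey_year"]
            if ycol in df.columns and not pd.isna(row[ycol]):
                year = int(row[ycol])
                lo, hi = survey_year_window
                if not lo <= year <= hi:
                    raise ValueError(
                        f"survey year {year} for {iso3} outside inclusion window {lo}-{hi}"
                    )
            label = ""
            scol = columns["source_label"]
            if scol in df.columns and not pd.isna(row[scol]):
                label = str(row[scol])
            survey = SurveyObservation(pct / 100.0, year, label)

        records.append(
            CountryRecord(
                iso3=iso3,
                name=str(row[columns["name"]]),
                factors=factors,
                adult_population=population,
                survey=survey,
            )
        )
    return WorldTable(tuple(records), reference_year=reference_year)


def write_country_table(table: WorldTable, target: Union[str, IO[str]]) -> None:
    """Write a country table as CSV (prevalence in percent, full precision)."""
    rows = []
    for r in table.records:
        rows.append(
            {
                "iso3": r.iso3,
                "name": r.name,
                "who_region": r.factors.who_region.value,
                "income_group": r.factors.income_group.value,
                "legal_status": r.factors.legal_status.value,
                "adult_population": r.adult_population,
                "prevalence_pct": (
                    repr(r.survey.prevalence * 100.0) if r.survey else ""
                ),
                "survey_year": (
                    r.survey.survey_year
                    if r.survey and r.survey.survey_year is not None
                    else ""
                ),
                "source_label": r.survey.source_label if r.survey else "",
            }
        )
    pd.DataFrame(rows).to_csv(target, index=False)


def read_market_index(source: Union[str, IO[str]], base_year: int = 2018) -> MarketIndexSeries:
    """Read a two-column (year, index_pct) CSV into a :class:`MarketIndexSeries`."""
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ValueError("market index file needs two columns: year, index_pct")
    years = df.iloc[:, 0].astype(int)
    values = df.iloc[:, 1].astype(float)
    if years.duplicated().any():
        dupes = sorted(years[years.duplicated()].unique())
        raise ValueError(f"duplicate year(s) in market index: {dupes}")
    return MarketIndexSeries(dict(zip(years, values)), base_year=base_year)


def write_market_index(series: MarketIndexSeries, target: Union[str, IO[str]]) -> None:
    pd.DataFrame(
        {"year": series.years, "index_pct": [series.points[y] for y in series.years]}
    ).to_csv(target, index=False)


# ---------------------------------------------------------------------------
# Coverage

def coverage_summary(table: WorldTable, by: str = "world") -> pd.DataFrame:
    """Adult population in surveyed vs unsurveyed countries, per group.

    ``by`` is ``"world"`` or a factor name. Each row reports the surveyed and
    unsurveyed adult populations of the group and their percentages of the
    group total (rounded half-up to 2 dp; they sum to 100 up to rounding).
    """
    if by != "world" and by not in FACTOR_NAMES:
        raise ValueError(f"unknown grouping {by!r}; expected 'world' or one of {FACTOR_NAMES}")

    def label_of(record: CountryRecord) -> str:
        if by == "world":
            return "World"
        return record.factors.get(by).value

    groups: dict[str, list[CountryRecord]] = {}
    for r in table.records:
        groups.setdefault(label_of(r), []).append(r)

    if by == "world":
        order = [label for label in ["World"] if label in groups]
    else:
        order = [m.value for m in _FACTOR_ENUMS[by] if m.value in groups]

    rows = []
    for label in order:
        recs = groups[label]
        surveyed_pop = sum(r.adult_population for r in recs if r.surveyed)
        unsurveyed_pop = sum(r.adult_population for r in recs if not r.surveyed)
        total = surveyed_pop + unsurveyed_pop
        rows.append(
            {
                "group": label,
                "surveyed_population": surveyed_pop,
                "surveyed_pct": round_half_up(100.0 * surveyed_pop / total, 2) if total else 0.0,
                "unsurveyed_population": unsurveyed_pop,
                "unsurveyed_pct": round_half_up(100.0 * unsurveyed_pop / total, 2) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
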