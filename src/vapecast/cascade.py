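"""The average-similarity imputation cascade.

A country's unknown vaping prevalence is imputed with the mean observed
prevalence of surveyed countries that share its factor subgroup. Subgroups
are tried in a fixed order of factor *signatures*, from most to least
specific; each step fills only the blanks left by the previous step, and a
terminal global mean guarantees full coverage whenever at least one survey
exists.

The default cascade order is::

    1. region x income x legal      (three-factor subgroup)
    2. income x legal
    3. income x region
    4. region x legal
    5. income
    6. global mean over all surveyed countries

A country whose factor is "unknown" cannot form a key at any level whose
signature includes that factor; it falls through to later levels. Group
means are unweighted across countries (one value per country); population
weighting is available behind a flag. A simplified confidence interval —
mean +/- z * sd / sqrt(n), truncated below at zero — accompanies each group
mean as a goodness-of-fit characteristic when the group has n >= 2.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Optional

from .country_data import FACTOR_NAMES, CountryRecord, WorldTable

__all__ = [
    "GroupKey",
    "GroupStat",
    "CascadeSpec",
    "ImputedPrevalence",
    "DEFAULT_CASCADE",
    "compute_group_stats",
    "cascade_impute",
    "goodness_of_fit_interval",
    "cascade_coverage_report",
]

Signature = tuple[str, ...]


def _normalize_signature(signature) -> Signature:
    sig = tuple(signature)
    for factor in sig:
        if factor not in FACTOR_NAMES:
            raise ValueError(f"unknown factor {factor!r} in signature; expected {FACTOR_NAMES}")
    if len(set(sig)) != len(sig):
        raise ValueError(f"repeated factor in signature {sig}")
    # canonical factor order keeps keys comparable regardless of spelling order
    return tuple(f for f in FACTOR_NAMES if f in sig)


@dataclass(frozen=True)
class GroupKey:
    """A level assignment for a subset of the three factors."""

    signature: Signature
    levels: tuple[str, ...]

    def __str__(self) -> str:
        if not self.signature:
            return "global"
        return ";".join(f"{f}={v}" for f, v in zip(self.signature, self.levels))


def key_for(record: CountryRecord, signature: Signature) -> Optional[GroupKey]:
    """Build the record's key for ``signature``; None if any factor is unknown."""
    sig = _normalize_signature(signature)
    levels = []
    for factor in sig:
        if not record.factors.is_known(factor):
            return None
        levels.append(record.factors.get(factor).value)
    return GroupKey(sig, tuple(levels))


@dataclass(frozen=True)
class GroupStat:
    """Mean, size and sample standard deviation of observed prevalence in a subgroup."""

    mean_prevalence: float
    n: int
    sd: Optional[float]  # sample (n-1) sd; None when n < 2


@dataclass(frozen=True)
class CascadeSpec:
    """Ordered factor signatures; the last must be empty (global mean)."""

    signatures: tuple[Signature, ...] = (
        ("who_region", "income_group", "legal_status"),
        ("income_group", "legal_status"),
        ("who_region", "income_group"),
        ("who_region", "legal_status"),
        ("income_group",),
        (),
    )

    def __post_init__(self) -> None:
        sigs = tuple(_normalize_signature(s) for s in self.signatures)
        if not sigs or sigs[-1] != ():
            raise ValueError("cascade must terminate with the empty (global) signature")
        object.__setattr__(self, "signatures", sigs)

    @property
    def n_levels(self) -> int:
        """Number of imputation levels (levels 1..n; level 0 is observed data)."""
        return len(self.signatures)


DEFAULT_CASCADE = CascadeSpec()


@dataclass(frozen=True)
class ImputedPrevalence:
    """A prevalence value with its provenance in the cascade.

    ``level`` 0 means observed from a survey; levels 1..k-1 are cascade steps
    in spec order; the last level is the global mean. ``fit_interval`` is the
    goodness-of-fit interval of the imputing group mean, when available.
    """

    value: float
    level: int
    group_key: Optional[GroupKey] = None
    fit_interval: Optional[tuple[float, float]] = None


def compute_group_stats(
    table: WorldTable,
    signature,
    population_weighted: bool = False,
) -> dict[GroupKey, GroupStat]:
    """Group statistics of observed prevalence for one factor signature.

    One :class:`GroupStat` per key having at least one surveyed country whose
    signature factors are all non-unknown. The mean is the unweighted
    arithmetic mean over contributing countries (one value per country)
    unless ``population_weighted`` is set.
    """
    sig = _normalize_signature(signature)
    contributions: dict[GroupKey, list[CountryRecord]] = {}
    for record in table.surveyed:
        key = key_for(record, sig)
        if key is None:
            continue
        contributions.setdefault(key, []).append(record)

    stats: dict[GroupKey, GroupStat] = {}
    for key, recs in contributions.items():
        values = [r.survey.prevalence for r in recs]
        if population_weighted:
            weights = [r.adult_population for r in recs]
            total = sum(weights)
            mean = (
                sum(v * w for v, w in zip(values, weights)) / total
                if total > 0
                else statistics.fmean(values)
            )
        elif min(values) == max(values):
            # all contributors agree: the mean is that value, bit-exact, so
            # zero-variance groups impute with no floating-point drift
            mean = values[0]
        else:
            mean = statistics.fmean(values)
        sd = statistics.stdev(values) if len(values) >= 2 else None
        stats[key] = GroupStat(mean_prevalence=mean, n=len(values), sd=sd)
    return stats


def goodness_of_fit_interval(
    stat: GroupStat, z: float = 1.96
) -> Optional[tuple[float, float]]:
    """Simplified confidence interval for a group mean.

    ``mean +/- z * sd / sqrt(n)``, truncated below at 0. None when the group
    has fewer than two contributors (sd undefined) — flagged rather than
    fabricated.
    """
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    if stat.n < 2 or stat.sd is None:
        return None
    half = z * stat.sd / math.sqrt(stat.n)
    return (max(0.0, stat.mean_prevalence - half), stat.mean_prevalence + half)


def cascade_impute(
    table: WorldTable,
    spec: CascadeSpec = DEFAULT_CASCADE,
    z: float = 1.96,
    min_group_n: int = 1,
    population_weighted: bool = False,
) -> dict[str, ImputedPrevalence]:
    """Fill every country's prevalence through the fallback cascade.

    Surveyed countries keep their observed value untouched at level 0. An
    unsurveyed country receives the group mean of the first signature (in
    spec order) for which its key exists with at least ``min_group_n``
    contributing surveys; the terminal global mean covers any remainder.

    Raises
    ------
    ValueError
        If the table contains no surveyed country (no basis for any mean).
    """
    if not table.surveyed:
        raise ValueError("cannot impute: table has no surveyed country")

    level_stats = [
        compute_group_stats(table, sig, population_weighted=population_weighted)
        for sig in spec.signatures
    ]

    result: dict[str, ImputedPrevalence] = {}
    for record in table.records:
        if record.surveyed:
            result[record.iso3] = ImputedPrevalence(
                value=record.survey.prevalence, level=0
            )
            continue
        for step, (sig, stats) in enumerate(zip(spec.signatures, level_stats), start=1):
            key = key_for(record, sig)
            if key is None or key not in stats:
                continue
            stat = stats[key]
            if stat.n < min_group_n and sig != ():
                continue  # the terminal global mean is exempt, guaranteeing coverage
            result[record.iso3] = ImputedPrevalence(
                value=stat.mean_prevalence,
                level=step,
                group_key=key,
                fit_interval=goodness_of_fit_interval(stat, z=z),
            )
            break
        else:  # unreachable: the global key always exists when surveys exist
            raise AssertionError(f"cascade failed to cover {record.iso3}")
    return result


@dataclass
class CoverageReport:
    """Countries per provenance level and cumulative coverage per step."""

    counts: dict[int, int]
    cumulative: list[int]
    total: int

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.total


def cascade_coverage_report(
    result: dict[str, ImputedPrevalence], n_levels: int = DEFAULT_CASCADE.n_levels
) -> CoverageReport:
    """Count countries by provenance level and the cumulative fill sequence.

    ``cumulative[k]`` is the number of countries with a value after step k
    (k = 0 counts the surveyed countries); the sequence is non-decreasing and
    ends at the total number of countries.
    """
    if not result:
        raise ValueError("empty imputation result")
    counts: dict[int, int] = {}
    for imp in result.values():
        counts[imp.level] = counts.get(imp.level, 0) + 1
    max_level = max(max(counts), n_levels)
    cumulative = []
    running = 0
    for level in range(max_level + 1):
        running += counts.get(level, 0)
        cumulative.append(running)
    return CoverageReport(counts=counts, cumulative=cumulative, total=len(result))
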