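"""Synthetic country tables with known ground truth.

The generator emulates the statistical structure the estimation pipeline
assumes: ~200 countries/territories classified by WHO region, World Bank
income group and e-cigarette legal status; true vaping prevalence follows a
logit-additive model (baseline log-odds plus factor effects plus
country-level noise), so "similar countries have similar prevalence" is
literally true and the within-group noise sd controls how badly that
assumption fails. Adult populations are log-normal per income group, and
survey availability depends on income group only — emulating the real
coverage bias in which high-income populations are surveyed at ~87% while
low-income populations are surveyed at under 6%.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded explicitly; replicate ``r`` of an experiment uses ``seed + r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Optional

import numpy as np

from .aggregate import world_total
from .cascade import DEFAULT_CASCADE, CascadeSpec, cascade_impute
from .country_data import (
    CountryRecord,
    FactorValue,
    IncomeGroup,
    LegalStatus,
    SurveyObservation,
    WhoRegion,
    WorldTable,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "RecoverySummary",
    "generate_world",
    "recovery_experiment",
]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# Factor marginals loosely follow the observed composition of the world's
# ~200 countries; small "unknown" masses exercise the Unknown report rows.
_DEFAULT_REGION_MARGINALS = {
    "African": 0.25,
    "Eastern Mediterranean": 0.11,
    "European": 0.27,
    "Americas": 0.18,
    "South-East Asia": 0.06,
    "Western Pacific": 0.12,
    "unknown": 0.01,
}
_DEFAULT_INCOME_MARGINALS = {
    "high": 0.29,
    "upper middle": 0.29,
    "lower middle": 0.25,
    "low": 0.165,
    "unknown": 0.005,
}
_DEFAULT_LEGAL_MARGINALS = {
    "allowed": 0.385,
    "banned": 0.19,
    "no specific law": 0.425,
}

# Additive effects on the log-odds scale, sized so subgroup prevalences span
# roughly 0.2-7%: richer, permissive countries vape more.
_DEFAULT_REGION_EFFECTS = {
    "African": -0.5,
    "Eastern Mediterranean": 0.2,
    "European": 0.3,
    "Americas": 0.3,
    "South-East Asia": -0.7,
    "Western Pacific": 0.05,
    "unknown": 0.0,
}
_DEFAULT_INCOME_EFFECTS = {
    "high": 0.5,
    "upper middle": 0.05,
    "lower middle": -0.8,
    "low": -0.9,
    "unknown": 0.0,
}
_DEFAULT_LEGAL_EFFECTS = {
    "allowed": 0.3,
    "banned": -0.35,
    "no specific law": 0.0,
    "unknown": 0.0,
}

# Log-normal adult population (15+) parameters per income group; exp(16.8)
# is about 2e7 persons, and three sigmas span roughly 1e5 to 1e9.
_DEFAULT_POPULATION_LOGNORMAL = {
    "high": (16.0, 1.5),
    "upper middle": (16.6, 1.7),
    "lower middle": (16.8, 1.8),
    "low": (16.2, 1.3),
    "unknown": (16.0, 1.5),
}

# Probability a country has a qualifying survey, by income group: the
# coverage bias of real survey availability.
_DEFAULT_SURVEY_PROB = {
    "high": 0.87,
    "upper middle": 0.77,
    "lower middle": 0.09,
    "low": 0.055,
    "unknown": 0.25,
}


def _check_marginals(marginals: dict[str, float], what: str) -> None:
    for level, p in marginals.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{what} probability for {level!r} outside [0, 1]: {p}")
    total = sum(marginals.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"{what} marginals must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_countries: int = 201
    region_marginals: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_MARGINALS)
    )
    income_marginals: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INCOME_MARGINALS)
    )
    legal_marginals: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LEGAL_MARGINALS)
    )
    baseline_logodds: float = _logit(0.012)
    region_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_EFFECTS)
    )
    income_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INCOME_EFFECTS)
    )
    legal_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LEGAL_EFFECTS)
    )
    noise_sd: float = 0.5  # country-level noise on the log-odds scale
    population_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_POPULATION_LOGNORMAL)
    )
    survey_prob: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SURVEY_PROB)
    )
    survey_noise_sd: float = 0.0  # sd of measurement noise on observed prevalence
    survey_prob_fn: Optional[Callable[[str, int], float]] = None
    # optional hook: (income_group, adult_population) -> survey probability,
    # overriding survey_prob, for population-size-dependent masking
    reference_year: int = 2018
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if self.noise_sd < 0 or self.survey_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        _check_marginals(self.region_marginals, "region")
        _check_marginals(self.income_marginals, "income")
        _check_marginals(self.legal_marginals, "legal")
        for level, p in self.survey_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survey probability for {level!r} outside [0, 1]: {p}")


@dataclass
class SyntheticWorld:
    """An observed table (prevalence masked where unsurveyed) plus hidden truth."""

    observed: WorldTable
    truth: dict[str, float]


def _iso3(index: int) -> str:
    letters = []
    for _ in range(3):
        letters.append(chr(ord("A") + index % 26))
        index //= 26
    return "".join(reversed(letters))


def generate_world(config: SyntheticConfig = SyntheticConfig()) -> SyntheticWorld:
    """Draw one synthetic world; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    def draw(marginals: dict[str, float]) -> str:
        levels = list(marginals)
        probs = np.asarray([marginals[l] for l in levels], dtype=float)
        return str(rng.choice(levels, p=probs / probs.sum()))

    records = []
    truth: dict[str, float] = {}
    for i in range(config.n_countries):
        iso3 = _iso3(i)
        region = draw(config.region_marginals)
        income = draw(config.income_marginals)
        legal = draw(config.legal_marginals)

        logodds = (
            config.baseline_logodds
            + config.region_effects.get(region, 0.0)
            + config.income_effects.get(income, 0.0)
            + config.legal_effects.get(legal, 0.0)
        )
        if config.noise_sd > 0:
            logodds += rng.normal(0.0, config.noise_sd)
        prevalence = _inv_logit(logodds)

        loc, scale = config.population_lognormal.get(income, (16.0, 1.5))
        population = max(1, int(rng.lognormal(loc, scale)))

        if config.survey_prob_fn is not None:
            p_survey = config.survey_prob_fn(income, population)
        else:
            p_survey = config.survey_prob.get(income, 0.0)
        surveyed = bool(rng.random() < p_survey)

        survey = None
        if surveyed:
            observed_prev = prevalence
            if config.survey_noise_sd > 0:
                observed_prev = float(
                    np.clip(
                        prevalence + rng.normal(0.0, config.survey_noise_sd),
                        1e-6,
                        1.0 - 1e-6,
                    )
                )
            survey = SurveyObservation(
                prevalence=observed_prev,
                survey_year=config.reference_year,
                source_label="synthetic",
            )

        records.append(
            CountryRecord(
                iso3=iso3,
                name=f"Synthetica-{iso3}",
                factors=FactorValue(
                    who_region=WhoRegion(region),
                    income_group=IncomeGroup(income),
                    legal_status=LegalStatus(legal),
                ),
                adult_population=population,
                survey=survey,
            )
        )
        truth[iso3] = prevalence

    return SyntheticWorld(
        observed=WorldTable(tuple(records), reference_year=config.reference_year),
        truth=truth,
    )


@dataclass
class RecoverySummary:
    """Bias/RMSE of the estimated world total against the known truth."""

    n_reps: int
    relative_bias: float  # mean of (estimate - truth) / truth
    relative_rmse: float  # sqrt(mean of squared relative errors)
    mean_true_total: float
    mean_estimated_total: float
    per_level_mean_abs_error: dict[int, float]
    # mean |imputed - true| prevalence (fraction) per provenance level
    relative_errors: list[float]


def recovery_experiment(
    config: SyntheticConfig = SyntheticConfig(),
    n_reps: int = 20,
    spec: CascadeSpec = DEFAULT_CASCADE,
) -> RecoverySummary:
    """Generate-impute-aggregate repeatedly and score total recovery.

    Replicate ``r`` regenerates the world with ``seed + r``, runs the full
    cascade on the masked table, and compares the estimated world total with
    the total implied by the hidden true prevalences.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rel_errors: list[float] = []
    true_totals: list[float] = []
    est_totals: list[float] = []
    level_abs_err: dict[int, list[float]] = {}

    for rep in range(n_reps):
        world = generate_world(replace(config, seed=config.seed + rep))
        table = world.observed
        result = cascade_impute(table, spec=spec)

        est = world_total(result, table)
        true = sum(
            Fraction(world.truth[r.iso3]) * r.adult_population for r in table.records
        )
        est_f, true_f = float(est), float(true)
        rel_errors.append((est_f - true_f) / true_f)
        true_totals.append(true_f)
        est_totals.append(est_f)

        for record in table.records:
            imp = result[record.iso3]
            level_abs_err.setdefault(imp.level, []).append(
                abs(imp.value - world.truth[record.iso3])
            )

    errors = np.asarray(rel_errors)
    return RecoverySummary(
        n_reps=n_reps,
        relative_bias=float(errors.mean()),
        relative_rmse=float(np.sqrt((errors**2).mean())),
        mean_true_total=float(np.mean(true_totals)),
        mean_estimated_total=float(np.mean(est_totals)),
        per_level_mean_abs_error={
            level: float(np.mean(v)) for level, v in sorted(level_abs_err.items())
        },
        relative_errors=rel_errors,
    )
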