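"""Pipeline orchestration and report rendering.

``run_estimate`` ties the stages together: read and validate the country
table, compute survey-coverage summaries, run the imputation cascade,
scale to user counts and aggregate into the standard breakdowns (income,
region, legal status, surveyed/estimated). ``run_project`` carries a
base-year world total forward along a market-revenue index. Both are pure
functions of their inputs; the CLI is a thin shell over them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import aggregate as agg
from .cascade import (
    DEFAULT_CASCADE,
    CascadeSpec,
    cascade_coverage_report,
    cascade_impute,
    compute_group_stats,
    goodness_of_fit_interval,
)
from .country_data import (
    FACTOR_NAMES,
    MarketIndexSeries,
    WorldTable,
    coverage_summary,
    read_country_table,
    read_market_index,
)
from .projection import ProjectionConfig, projection_table

logger = logging.getLogger("vapecast")

__all__ = ["RunConfig", "EstimateBundle", "run_estimate", "run_project", "load_run_config"]


@dataclass
class RunConfig:
    countries_path: Optional[str] = None
    index_path: Optional[str] = None
    column_mapping: dict[str, str] = field(default_factory=dict)
    survey_year_window: tuple[int, int] = (2012, 2020)
    reference_year: int = 2018
    cascade: CascadeSpec = DEFAULT_CASCADE
    z: float = 1.96
    min_group_n: int = 1
    population_weighted: bool = False
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)


def load_run_config(path: str) -> RunConfig:
    """Load a YAML run configuration; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = RunConfig()
    config.countries_path = raw.get("countries", config.countries_path)
    config.index_path = raw.get("index", config.index_path)
    config.column_mapping = raw.get("columns", {}) or {}
    if "survey_year_window" in raw:
        lo, hi = raw["survey_year_window"]
        config.survey_year_window = (int(lo), int(hi))
    config.reference_year = int(raw.get("reference_year", config.reference_year))
    if "cascade" in raw:
        config.cascade = CascadeSpec(tuple(tuple(sig) for sig in raw["cascade"]))
    config.z = float(raw.get("z", config.z))
    config.min_group_n = int(raw.get("min_group_n", config.min_group_n))
    config.population_weighted = bool(
        raw.get("population_weighted", config.population_weighted)
    )
    proj = raw.get("projection", {}) or {}
    config.projection = ProjectionConfig(
        base_year=int(proj.get("base_year", 2018)),
        mode=str(proj.get("mode", "index")),
        rho=float(proj.get("rho", 0.933)),
    )
    return config


@dataclass
class EstimateBundle:
    """Everything the estimation stage reports."""

    table: WorldTable
    coverage: dict[str, pd.DataFrame]  # "world" plus one frame per factor
    group_stats: pd.DataFrame  # per-factor subgroup means (single-factor signatures)
    provenance: pd.DataFrame  # iso3, value_pct, level, group_key, interval
    estimates: dict[str, pd.DataFrame]  # rounded report tables per partition
    estimate_rows: dict[str, list[agg.EstimateRow]]  # exact rows per partition
    world_total: Fraction
    cumulative_coverage: list[int]


def _group_stats_frame(table: WorldTable, z: float, population_weighted: bool) -> pd.DataFrame:
    rows = []
    for factor in FACTOR_NAMES:
        stats = compute_group_stats(table, (factor,), population_weighted=population_weighted)
        for key in sorted(stats, key=lambda k: k.levels):
            stat = stats[key]
            interval = goodness_of_fit_interval(stat, z=z)
            rows.append(
                {
                    "factor": factor,
                    "group": key.levels[0],
                    "n_surveys": stat.n,
                    "mean_prevalence_pct": round(stat.mean_prevalence * 100.0, 4),
                    "interval_low_pct": round(interval[0] * 100.0, 4) if interval else None,
                    "interval_high_pct": round(interval[1] * 100.0, 4) if interval else None,
                }
            )
    return pd.DataFrame(rows)


def run_estimate(
    config: RunConfig, table: Optional[WorldTable] = None
) -> EstimateBundle:
    """Run the full estimation pipeline; deterministic for fixed inputs.

    ``table`` may be passed directly (e.g. a synthetic world); otherwise it
    is read from ``config.countries_path``.
    """
    if table is None:
        if not config.countries_path:
            raise ValueError("estimate stage: no country table given")
        try:
            table = read_country_table(
                config.countries_path,
                schema_config=config.column_mapping,
                survey_year_window=config.survey_year_window,
                reference_year=config.reference_year,
            )
        except Exception as exc:
            raise ValueError(f"estimate stage: reading country table failed: {exc}") from exc

    coverage = {"world": coverage_summary(table, "world")}
    for factor in FACTOR_NAMES:
        coverage[factor] = coverage_summary(table, factor)

    try:
        result = cascade_impute(
            table,
            spec=config.cascade,
            z=config.z,
            min_group_n=config.min_group_n,
            population_weighted=config.population_weighted,
        )
    except ValueError as exc:
        raise ValueError(f"imputation stage: {exc}") from exc

    report = cascade_coverage_report(result, n_levels=config.cascade.n_levels)
    logger.info(
        "cascade cumulative coverage per step: %s of %d countries",
        report.cumulative,
        report.total,
    )

    prov_rows = []
    for iso3 in sorted(result):
        imp = result[iso3]
        low, high = imp.fit_interval if imp.fit_interval else (None, None)
        prov_rows.append(
            {
                "iso3": iso3,
                "value_pct": imp.value * 100.0,
                "level": imp.level,
                "group_key": str(imp.group_key) if imp.group_key else "",
                "interval_low_pct": low * 100.0 if low is not None else None,
                "interval_high_pct": high * 100.0 if high is not None else None,
            }
        )

    partitions = ["world", *FACTOR_NAMES, agg.SURVEY_PARTITION]
    estimate_rows = {p: agg.aggregate_estimates(result, table, by=p) for p in partitions}
    estimates = {p: agg.estimates_frame(rows) for p, rows in estimate_rows.items()}

    return EstimateBundle(
        table=table,
        coverage=coverage,
        group_stats=_group_stats_frame(table, config.z, config.population_weighted),
        provenance=pd.DataFrame(prov_rows),
        estimates=estimates,
        estimate_rows=estimate_rows,
        world_total=estimate_rows["world"][0].n_vapers,
        cumulative_coverage=report.cumulative,
    )


def run_project(
    config: RunConfig,
    base_total: float,
    series: Optional[MarketIndexSeries] = None,
) -> pd.DataFrame:
    """Project a base-year total to every year of the index, both modes."""
    if series is None:
        if not config.index_path:
            raise ValueError("projection stage: no market index given")
        try:
            series = read_market_index(config.index_path, base_year=config.projection.base_year)
        except Exception as exc:
            raise ValueError(f"projection stage: reading market index failed: {exc}") from exc
    return projection_table(base_total, series, config.projection)


def format_estimates_text(frame: pd.DataFrame, title: str) -> str:
    """Aligned text rendering with thousands separators."""
    lines = [title]
    width = max((len(str(g)) for g in frame["group"]), default=10) + 2
    lines.append(f"{'group':<{width}}{'countries':>10}{'vapers':>16}")
    for _, row in frame.iterrows():
        lines.append(
            f"{row['group']:<{width}}{row['n_countries']:>10,}{row['n_vapers']:>16,}"
        )
    return "\n".join(lines)
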