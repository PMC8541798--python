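"""Market-index calibration and forward projection of the global user total.

The market-revenue index (revenue by year, in percent of a base year) is
calibrated so the base year reads exactly 100%; the global number of users
estimated for the base year is then scaled by the index ratio of a target
year. Two projection modes are provided:

``index``
    total x ratio(target). The default: the raw revenue ratio carries the
    total forward, assuming user numbers move proportionally with revenue.
``correlation_damped``
    total x (1 + rho * (ratio(target) - 1)), shrinking the index's relative
    change toward zero by a revenue-prevalence correlation coefficient rho
    (default 0.933, estimated from a long national revenue/prevalence
    series). For rho in (0, 1) this always lies between the base total and
    the index-mode projection.

The two modes disagree for years away from the base (e.g. ~68.0 m vs
~67.3 m for a 17% revenue rise); reporting surfaces both rather than
silently resolving the ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd
from scipy import stats as _scipy_stats

from .country_data import MarketIndexSeries

__all__ = [
    "ProjectionConfig",
    "calibrate",
    "project_total",
    "pearson_correlation",
    "projection_table",
]

_MODES = ("index", "correlation_damped")


@dataclass(frozen=True)
class ProjectionConfig:
    base_year: int = 2018
    mode: str = "index"
    rho: float = 0.933  # used only in correlation_damped mode

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")


def calibrate(series: MarketIndexSeries, base_year: int) -> MarketIndexSeries:
    """Rescale the series so the base year reads exactly 100%.

    Idempotent: calibrating an already-calibrated series at the same year is
    the identity.
    """
    if base_year not in series.points:
        raise KeyError(
            f"base year {base_year} not in series (years {series.years})"
        )
    base = series.points[base_year]
    points = {year: 100.0 * value / base for year, value in series.points.items()}
    points[base_year] = 100.0  # exact, immune to rounding in the division
    return MarketIndexSeries(points, base_year=base_year)


def project_total(
    total: float,
    series: MarketIndexSeries,
    target_year: int,
    config: ProjectionConfig = ProjectionConfig(),
) -> float:
    """Project a base-year user total to ``target_year`` along the index.

    At the base year both modes return ``total`` exactly.
    """
    if target_year not in series.points:
        raise KeyError(
            f"target year {target_year} not in series (years {series.years})"
        )
    ratio = series.ratio(target_year, base_year=config.base_year)
    if config.mode == "index":
        return total * ratio
    return total * (1.0 + config.rho * (ratio - 1.0))


def pearson_correlation(
    series_a: Mapping[int, float], series_b: Mapping[int, float]
) -> float:
    """Product-moment correlation of two year-indexed series on their overlap.

    Requires at least three overlapping years and non-constant values on the
    overlap. This is the diagnostic used to justify (and dampen) the
    revenue-based projection where a per-capita revenue series and a
    prevalence series are both available.
    """
    years = sorted(set(series_a) & set(series_b))
    if len(years) < 3:
        raise ValueError(
            f"need >= 3 overlapping years, got {len(years)}"
        )
    a = [series_a[y] for y in years]
    b = [series_b[y] for y in years]
    if len(set(a)) == 1 or len(set(b)) == 1:
        raise ValueError("series constant on the overlapping years; correlation undefined")
    return float(_scipy_stats.pearsonr(a, b).statistic)


def projection_table(
    total: float,
    series: MarketIndexSeries,
    config: ProjectionConfig = ProjectionConfig(),
) -> pd.DataFrame:
    """Projected totals for every year of the series, both modes side by side."""
    calibrated = calibrate(series, config.base_year)
    rows = []
    for year in calibrated.years:
        rows.append(
            {
                "year": year,
                "index_pct": calibrated.points[year],
                "projected_index": project_total(
                    total, calibrated, year, replace(config, mode="index")
                ),
                "projected_damped": project_total(
                    total, calibrated, year, replace(config, mode="correlation_damped")
                ),
            }
        )
    return pd.DataFrame(rows)
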