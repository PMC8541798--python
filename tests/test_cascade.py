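"""The average-similarity cascade: group means, fallback order, provenance."""

import math
import statistics

import numpy as np
import pytest

from vapecast.cascade import (
    DEFAULT_CASCADE,
    CascadeSpec,
    cascade_coverage_report,
    cascade_impute,
    compute_group_stats,
    goodness_of_fit_interval,
    key_for,
)
from vapecast.country_data import (
    IncomeGroup,
    LegalStatus,
    SurveyObservation,
    WhoRegion,
    WorldTable,
)

from conftest import brute_force_impute, make_record, random_table


class TestGroupStats:
    def test_single_country_group(self):
        table = WorldTable((make_record("AAA", prevalence=0.05),))
        stats = compute_group_stats(table, ("income_group",))
        (stat,) = stats.values()
        assert stat.mean_prevalence == 0.05
        assert stat.n == 1
        assert stat.sd is None

    def test_three_country_group_mean_and_sd(self):
        """Prevalences 1%, 2%, 3%: mean 2%, sd one percentage point."""
        table = WorldTable(
            (
                make_record("AAA", prevalence=0.01),
                make_record("BBB", prevalence=0.02),
                make_record("CCC", prevalence=0.03),
            )
        )
        stats = compute_group_stats(table, ("income_group",))
        (stat,) = stats.values()
        assert stat.mean_prevalence == pytest.approx(0.02)
        assert stat.n == 3
        assert stat.sd == pytest.approx(0.01)

    def test_unknown_factor_excluded_from_grouping(self):
        table = WorldTable(
            (
                make_record("AAA", prevalence=0.01),
                make_record("BBB", prevalence=0.05, income=IncomeGroup.UNKNOWN),
            )
        )
        stats = compute_group_stats(table, ("income_group",))
        (stat,) = stats.values()
        assert stat.n == 1 and stat.mean_prevalence == 0.01

    def test_population_weighted_option(self):
        table = WorldTable(
            (
                make_record("AAA", prevalence=0.01, population=100),
                make_record("BBB", prevalence=0.03, population=300),
            )
        )
        stats = compute_group_stats(table, ("income_group",), population_weighted=True)
        (stat,) = stats.values()
        assert stat.mean_prevalence == pytest.approx((0.01 * 100 + 0.03 * 300) / 400)

    def test_empty_map_when_no_surveys(self):
        table = WorldTable((make_record("AAA"),))
        assert compute_group_stats(table, ("income_group",)) == {}


class TestGoodnessOfFit:
    def test_hand_arithmetic_interval(self):
        from vapecast.cascade import GroupStat

        interval = goodness_of_fit_interval(GroupStat(0.02, 4, 0.01), z=1.96)
        assert interval == pytest.approx((0.0102, 0.0298))

    def test_unavailable_below_two_contributors(self):
        from vapecast.cascade import GroupStat

        assert goodness_of_fit_interval(GroupStat(0.02, 1, None)) is None

    def test_degenerate_zero_sd(self):
        from vapecast.cascade import GroupStat

        assert goodness_of_fit_interval(GroupStat(0.02, 10, 0.0)) == (0.02, 0.02)

    def test_truncated_below_at_zero(self):
        from vapecast.cascade import GroupStat

        low, high = goodness_of_fit_interval(GroupStat(0.001, 4, 0.01), z=1.96)
        assert low == 0.0 and high > 0.001

    def test_nonpositive_z_rejected(self):
        from vapecast.cascade import GroupStat

        with pytest.raises(ValueError, match="positive"):
            goodness_of_fit_interval(GroupStat(0.02, 4, 0.01), z=0.0)


class TestCascadeImpute:
    def test_toy_world_levels_and_values(self, toy5):
        result = cascade_impute(toy5)
        assert result["AAA"].level == 0 and result["AAA"].value == 0.02
        assert result["BBB"].level == 0 and result["BBB"].value == 0.04
        assert result["CCC"].level == 1 and result["CCC"].value == pytest.approx(0.03)
        assert result["DDD"].level == 2 and result["DDD"].value == pytest.approx(0.03)
        assert result["EEE"].level == 6 and result["EEE"].value == pytest.approx(0.03)

    def test_all_surveyed_world_is_untouched(self):
        table = WorldTable(
            tuple(
                make_record(f"AA{c}", prevalence=p)
                for c, p in zip("ABC", (0.011, 0.022, 0.033))
            )
        )
        result = cascade_impute(table)
        for record in table.records:
            assert result[record.iso3].level == 0
            assert result[record.iso3].value == record.survey.prevalence

    def test_no_surveys_is_hard_error(self):
        table = WorldTable((make_record("AAA"), make_record("BBB")))
        with pytest.raises(ValueError, match="no surveyed"):
            cascade_impute(table)

    def test_interval_contains_value_when_present(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, 30)
        for imp in cascade_impute(table).values():
            if imp.fit_interval is not None:
                low, high = imp.fit_interval
                assert low <= imp.value <= high

    def test_min_group_n_skips_small_groups_but_global_still_covers(self, toy5):
        result = cascade_impute(toy5, min_group_n=3)
        # no subgroup reaches 3 surveys, so everything unsurveyed falls to global
        assert result["CCC"].level == DEFAULT_CASCADE.n_levels
        assert result["CCC"].value == pytest.approx(0.03)

    def test_spec_must_end_with_global_signature(self):
        with pytest.raises(ValueError, match="global"):
            CascadeSpec((("income_group",),))


class TestCascadeProperties:
    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            table = random_table(rng, int(rng.integers(2, 21)))
            if not table.surveyed:
                continue
            result = cascade_impute(table)
            expected = brute_force_impute(table)
            assert set(result) == set(expected)
            for iso3, (value, level) in expected.items():
                assert result[iso3].value == value
                assert result[iso3].level == level

    def test_completeness_and_never_overwrite(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            table = random_table(rng, 25, p_survey=0.3)
            if not table.surveyed:
                continue
            result = cascade_impute(table)
            assert set(result) == {r.iso3 for r in table.records}
            for record in table.surveyed:
                assert result[record.iso3].value == record.survey.prevalence
                assert result[record.iso3].level == 0

    def test_order_invariance(self):
        import random

        rng = np.random.default_rng(11)
        table = random_table(rng, 15)
        records = list(table.records)
        random.Random(0).shuffle(records)
        shuffled = WorldTable(tuple(records), reference_year=table.reference_year)
        assert shuffled == table
        assert cascade_impute(table) == cascade_impute(shuffled)

    def test_adding_a_survey_never_worsens_any_level(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            table = random_table(rng, 15, p_survey=0.4)
            if not table.surveyed or not table.unsurveyed:
                continue
            before = cascade_impute(table)
            target = table.unsurveyed[0]
            richer = table.with_survey(
                target.iso3, SurveyObservation(prevalence=0.02, survey_year=2018)
            )
            after = cascade_impute(richer)
            for record in table.records:
                if record.iso3 != target.iso3:
                    assert after[record.iso3].level <= before[record.iso3].level

    def test_zero_variance_recovery(self):
        """If true prevalence is a function of the full three-factor key and
        every key has a survey, imputation is error-free."""
        rng = np.random.default_rng(23)
        combos = [
            (r, i, l)
            for r in (WhoRegion.EUROPEAN, WhoRegion.AFRICAN)
            for i in (IncomeGroup.HIGH, IncomeGroup.LOW)
            for l in (LegalStatus.ALLOWED, LegalStatus.BANNED)
        ]
        records = []
        truth = {}
        for k, (region, income, legal) in enumerate(combos):
            p = 0.005 * (k + 1)
            for j in range(3):
                iso3 = f"{chr(ord('A') + k)}A{chr(ord('A') + j)}"
                surveyed = j == 0  # one survey per subgroup
                records.append(
                    make_record(
                        iso3,
                        region=region,
                        income=income,
                        legal=legal,
                        prevalence=p if surveyed else None,
                    )
                )
                truth[iso3] = p
        table = WorldTable(tuple(records))
        result = cascade_impute(table)
        for iso3, p in truth.items():
            assert result[iso3].value == p


class TestCoverageReport:
    def test_all_surveyed(self):
        table = WorldTable(
            tuple(make_record(f"AA{c}", prevalence=0.01) for c in "ABCD")
        )
        report = cascade_coverage_report(cascade_impute(table))
        assert report.counts == {0: 4}
        assert report.cumulative[0] == 4
        assert report.cumulative[-1] == 4

    def test_toy_world_counts(self, toy5):
        report = cascade_coverage_report(cascade_impute(toy5))
        assert report.counts == {0: 2, 1: 1, 2: 1, 6: 1}
        assert report.cumulative == [2, 3, 4, 4, 4, 4, 5]

    def test_cumulative_is_monotone_and_ends_at_total(self):
        rng = np.random.default_rng(31)
        table = random_table(rng, 50, p_survey=0.3)
        report = cascade_coverage_report(cascade_impute(table))
        assert sum(report.counts.values()) == report.total == 50
        assert all(a <= b for a, b in zip(report.cumulative, report.cumulative[1:]))
        assert report.cumulative[-1] == 50

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cascade_coverage_report({})
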