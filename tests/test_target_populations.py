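"""Eligibility rules: cohort filters, SAM caseload formulas, exclusions and
subtraction chains."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutricost.demographics import CohortTable
from nutricost.errors import ConfigurationError, InvalidInputError, ResolutionError
from nutricost.target_populations import (
    PrevalenceFilter,
    TargetRule,
    diarrhoea_treatment_target,
    eligible_mothers_cash_transfer,
    mnp_target,
    resolve_all,
    resolve_target,
    sam_caseload_india_plus,
    sam_caseload_sun,
)

from conftest import make_region


@pytest.fixture
def cohorts():
    return CohortTable(
        "toy",
        2014,
        {
            "children_6_59m": 1_000_000.0,
            "children_6_23m": 300_000.0,
            "pregnant_women": 50_000.0,
            "lactating_mothers_0_6m": 50_000.0,
        },
    )


class TestResolveTarget:
    def test_plain_cohort_rule_is_identity(self, cohorts, toy_region):
        rule = TargetRule(cohort="children_6_59m")
        assert resolve_target(rule, cohorts, toy_region) == 1_000_000.0

    def test_full_exclusion_gives_zero(self, cohorts, toy_region):
        rule = TargetRule(cohort="children_6_59m", exclusion_fraction=1.0)
        assert resolve_target(rule, cohorts, toy_region) == 0.0

    def test_endemic_only_outside_endemic_region(self, cohorts):
        rule = TargetRule(cohort="pregnant_women", endemic_only=True)
        non_endemic = make_region(endemic=False)
        endemic = make_region(endemic=True)
        assert resolve_target(rule, cohorts, non_endemic) == 0.0
        assert resolve_target(rule, cohorts, endemic) == 50_000.0

    def test_prevalence_filter_applies_region_prevalence(self, cohorts):
        demo = make_region(prev_whz_m3=0.05)
        rule = TargetRule(
            cohort="children_6_59m",
            prevalence_filter=PrevalenceFilter(indicator="whz_lt_m3", multiplier=2.0),
            inpatient_fraction=0.15,
        )
        assert resolve_target(rule, cohorts, demo) == pytest.approx(
            1_000_000 * 0.05 * 2 * 0.15
        )

    def test_govt_employment_exclusion_uses_region_share(self, cohorts):
        demo = make_region(frac_govt=0.10)
        rule = TargetRule(cohort="lactating_mothers_0_6m", exclude_govt_employed=True)
        assert resolve_target(rule, cohorts, demo) == pytest.approx(45_000.0)

    def test_subtraction_floors_at_zero(self, cohorts, toy_region):
        rule = TargetRule(cohort="children_6_23m", subtract_rule="cf")
        assert (
            resolve_target(rule, cohorts, toy_region, {"cf": 1e9}) == 0.0
        )
        assert resolve_target(rule, cohorts, toy_region, {"cf": 100_000.0}) == (
            200_000.0
        )

    def test_missing_cohort_is_resolution_error(self, cohorts, toy_region):
        with pytest.raises(ResolutionError):
            resolve_target(TargetRule(cohort="nope"), cohorts, toy_region)

    @given(
        exclusion=st.floats(min_value=0, max_value=1),
        reduction=st.floats(min_value=0, max_value=1),
        cohort_size=st.floats(min_value=0, max_value=1e7),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, exclusion, reduction, cohort_size):
        """Resolved targets never exceed cohort x incidence multiplier, never
        go negative, and shrink as exclusions/reductions grow."""
        cohorts = CohortTable("p", 2014, {"c": cohort_size})
        demo = make_region()
        rule = TargetRule(
            cohort="c",
            incidence_multiplier=2.0,
            exclusion_fraction=exclusion,
            expected_reduction=reduction,
        )
        value = resolve_target(rule, cohorts, demo)
        assert 0 <= value <= cohort_size * 2.0 + 1e-6
        laxer = TargetRule(cohort="c", incidence_multiplier=2.0)
        assert value <= resolve_target(laxer, cohorts, demo) + 1e-9


class TestResolveAll:
    def test_subtraction_resolved_in_dependency_order(self, cohorts, toy_region):
        rules = {
            "mnp": TargetRule(cohort="children_6_23m", subtract_rule="cf"),
            "cf": TargetRule(cohort="children_6_23m", exclusion_fraction=0.5),
        }
        resolved = resolve_all(rules, cohorts, toy_region)
        assert resolved["cf"] == pytest.approx(150_000.0)
        assert resolved["mnp"] == pytest.approx(150_000.0)

    def test_cycle_is_configuration_error(self, cohorts, toy_region):
        rules = {
            "a": TargetRule(cohort="children_6_23m", subtract_rule="b"),
            "b": TargetRule(cohort="children_6_23m", subtract_rule="a"),
        }
        with pytest.raises(ConfigurationError):
            resolve_all(rules, cohorts, toy_region)

    def test_dangling_reference_is_configuration_error(self, cohorts, toy_region):
        rules = {"a": TargetRule(cohort="children_6_23m", subtract_rule="ghost")}
        with pytest.raises(ConfigurationError):
            resolve_all(rules, cohorts, toy_region)


class TestSamCaseloads:
    def test_zero_prevalence_gives_zero(self):
        assert sam_caseload_india_plus(1e6, 0.0) == 0.0
        assert sam_caseload_sun(1e6, 0.0) == 0.0

    def test_inpatient_closed_form(self):
        assert sam_caseload_india_plus(1e6, 0.05) == pytest.approx(15_000)

    def test_national_caseload_scale(self):
        # ~108 million children at 6.4% severe wasting, doubled for incidence,
        # 15% inpatient: just over two million treated cases a year.
        assert sam_caseload_india_plus(108.1e6, 0.064) == pytest.approx(
            2.076e6, rel=5e-3
        )

    def test_cmam_definition_folds_reduction_and_cap(self):
        assert sam_caseload_sun(108.16e6, 0.064, 0.5, 0.8) == pytest.approx(
            5.54e6, rel=1e-2
        )

    def test_cmam_limit_recovers_raw_incidence(self):
        assert sam_caseload_sun(1e6, 0.05, reduction=0.0, coverage_cap=1.0) == (
            pytest.approx(sam_caseload_india_plus(1e6, 0.05, 2.0, 1.0))
        )

    @given(
        children=st.floats(min_value=0, max_value=2e8),
        prev=st.floats(min_value=0, max_value=1),
        reduction=st.floats(min_value=0, max_value=1),
        cap=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, deadline=None)
    def test_cmam_dominated_by_uncapped_caseload(self, children, prev, reduction, cap):
        capped = sam_caseload_sun(children, prev, reduction, cap)
        assert capped <= sam_caseload_sun(children, prev, 0.0, 1.0) + 1e-9

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            sam_caseload_india_plus(1e6, 1.5)


class TestSimpleTargets:
    @pytest.mark.parametrize(
        "mothers,frac,expected", [(1e6, 0.0, 1e6), (1e6, 1.0, 0.0)]
    )
    def test_cash_transfer_excludes_government_employees(
        self, mothers, frac, expected
    ):
        assert eligible_mothers_cash_transfer(mothers, frac) == expected

    def test_cash_transfer_invalid_fraction(self):
        with pytest.raises(InvalidInputError):
            eligible_mothers_cash_transfer(1e6, 1.2)

    @pytest.mark.parametrize("children,cf,expected", [(10, 4, 6), (4, 10, 0)])
    def test_mnp_subtracts_cf_recipients_floored(self, children, cf, expected):
        assert mnp_target(children, cf) == expected

    @pytest.mark.parametrize("children", [0.0, 1e6])
    def test_diarrhoea_target_is_cohort_identity(self, children):
        # Episode counts live in the annualized unit cost, not the target.
        assert diarrhoea_treatment_target(children) == children
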