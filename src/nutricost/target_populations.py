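"""Target-population resolution.

Each intervention declares a :class:`TargetRule`: the cohort it draws on,
an optional anthropometric prevalence filter, incidence and inpatient
multipliers, exclusions, an endemic-area restriction, and an optional
subtraction of another intervention's resolved target (for mutually exclusive
entitlements such as micronutrient powders vs complementary food).

Coverage fractions live in the costing engine, not here, with one deliberate
exception: the SUN community-based SAM treatment package folds its 80%
coverage ceiling into the *definition* of its target caseload, so
:func:`sam_caseload_sun` applies it.
"""

from __future__ import annotations

from graphlib import CycleError, TopologicalSorter
from typing import Dict, Literal, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .demographics import CohortTable, RegionDemographics
from .errors import ConfigurationError, InvalidInputError, ResolutionError

__all__ = [
    "PrevalenceFilter",
    "TargetRule",
    "diarrhoea_treatment_target",
    "eligible_mothers_cash_transfer",
    "mnp_target",
    "resolve_all",
    "resolve_target",
    "sam_caseload_india_plus",
    "sam_caseload_sun",
]

PrevalenceIndicator = Literal["waz_lt_m3", "whz_lt_m3", "whz_lt_m2"]

_INDICATOR_ATTR = {
    "waz_lt_m3": "prev_waz_lt_m3",
    "whz_lt_m3": "prev_whz_lt_m3",
    "whz_lt_m2": "prev_whz_lt_m2",
}


class PrevalenceFilter(BaseModel):
    """Restrict a cohort to the fraction below an anthropometric threshold.

    ``multiplier`` rescales the prevalence, e.g. doubling severe-wasting
    prevalence to approximate annual incident SAM cases from point prevalence.
    """

    model_config = ConfigDict(frozen=True)

    indicator: PrevalenceIndicator
    multiplier: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "PrevalenceFilter":
        if self.multiplier < 0:
            raise InvalidInputError("prevalence multiplier must be >= 0")
        return self


class TargetRule(BaseModel):
    """Eligibility rule mapping cohorts to beneficiary counts."""

    model_config = ConfigDict(frozen=True)

    cohort: str
    prevalence_filter: Optional[PrevalenceFilter] = None
    incidence_multiplier: float = Field(default=1.0, ge=0)
    inpatient_fraction: float = Field(default=1.0, ge=0, le=1)
    exclusion_fraction: float = Field(default=0.0, ge=0, le=1)
    endemic_only: bool = False
    subtract_rule: Optional[str] = None
    expected_reduction: float = Field(default=0.0, ge=0, le=1)
    #: Exclude women employed in the government sector at the region's own
    #: employment share (maternity-benefit eligibility).
    exclude_govt_employed: bool = False


def resolve_target(
    rule: TargetRule,
    cohorts: CohortTable,
    demo: RegionDemographics,
    resolved: Optional[Mapping[str, float]] = None,
) -> float:
    """Resolve one rule to a beneficiary count for one region.

    The count is
    ``cohort x prevalence x incidence x (1 - expected_reduction)
    x inpatient_fraction x (1 - exclusion_fraction)``,
    minus the referenced intervention's already-resolved target (floored at
    zero).  Endemic-only rules resolve to zero outside endemic regions.
    """
    if rule.cohort not in cohorts:
        raise ResolutionError(
            f"cohort {rule.cohort!r} not present for region {cohorts.region_id!r}"
        )
    if rule.endemic_only and not demo.malaria_endemic:
        return 0.0
    count = cohorts[rule.cohort]
    if rule.prevalence_filter is not None:
        prevalence = getattr(demo, _INDICATOR_ATTR[rule.prevalence_filter.indicator])
        count *= prevalence * rule.prevalence_filter.multiplier
    count *= (
        rule.incidence_multiplier
        * (1.0 - rule.expected_reduction)
        * rule.inpatient_fraction
        * (1.0 - rule.exclusion_fraction)
    )
    if rule.exclude_govt_employed:
        count *= 1.0 - demo.frac_women_govt
    if rule.subtract_rule is not None:
        if resolved is None or rule.subtract_rule not in resolved:
            raise ResolutionError(
                f"subtract_rule {rule.subtract_rule!r} has not been resolved"
            )
        count = max(count - resolved[rule.subtract_rule], 0.0)
    return count


def resolve_all(
    rules: Mapping[str, TargetRule],
    cohorts: CohortTable,
    demo: RegionDemographics,
) -> Dict[str, float]:
    """Resolve a set of rules, ordering subtraction dependencies topologically.

    Raises :class:`ConfigurationError` on cyclic or dangling ``subtract_rule``
    references.
    """
    graph: Dict[str, set] = {}
    for name, rule in rules.items():
        deps = set()
        if rule.subtract_rule is not None:
            if rule.subtract_rule not in rules:
                raise ConfigurationError(
                    f"rule {name!r} subtracts unknown rule {rule.subtract_rule!r}"
                )
            deps.add(rule.subtract_rule)
        graph[name] = deps
    try:
        order = list(TopologicalSorter(graph).static_order())
    except CycleError as exc:
        raise ConfigurationError(f"cyclic subtract_rule chain: {exc.args[1]}") from exc
    resolved: Dict[str, float] = {}
    for name in order:
        resolved[name] = resolve_target(rules[name], cohorts, demo, resolved)
    return resolved


def sam_caseload_india_plus(
    children_6_59m: float,
    prev_whz_lt_m3: float,
    incidence_multiplier: float = 2.0,
    inpatient_fraction: float = 0.15,
) -> float:
    """Annual inpatient SAM caseload under the facility-based treatment model.

    Annual incident cases are taken as twice the point prevalence of severe
    wasting (WHZ < -3); 15% of incident cases receive inpatient treatment.
    """
    _check_fraction("prev_whz_lt_m3", prev_whz_lt_m3)
    _check_fraction("inpatient_fraction", inpatient_fraction)
    if children_6_59m < 0 or incidence_multiplier < 0:
        raise InvalidInputError("children and multipliers must be >= 0")
    return children_6_59m * prev_whz_lt_m3 * incidence_multiplier * inpatient_fraction


def sam_caseload_sun(
    children_6_59m: float,
    prev_whz_lt_m3: float,
    reduction: float = 0.5,
    coverage_cap: float = 0.8,
) -> float:
    """Annual treated caseload under the community-based (CMAM) model.

    Incidence is again twice severe-wasting prevalence, but the package
    assumes delivering all preventive interventions first halves SAM
    prevalence, and "full coverage" means treating 80% of the remainder —
    both folded into the caseload definition.
    """
    _check_fraction("prev_whz_lt_m3", prev_whz_lt_m3)
    _check_fraction("reduction", reduction)
    _check_fraction("coverage_cap", coverage_cap)
    if children_6_59m < 0:
        raise InvalidInputError("children_6_59m must be >= 0")
    return children_6_59m * prev_whz_lt_m3 * 2.0 * (1.0 - reduction) * coverage_cap


def eligible_mothers_cash_transfer(
    lactating_mothers: float, frac_women_govt: float
) -> float:
    """Maternity-benefit eligibles: lactating mothers not in government jobs
    (government employees already receive paid maternity leave)."""
    _check_fraction("frac_women_govt", frac_women_govt)
    if lactating_mothers < 0:
        raise InvalidInputError("lactating_mothers must be >= 0")
    return lactating_mothers * (1.0 - frac_women_govt)


def mnp_target(children_6_23m: float, cf_recipients: float) -> float:
    """Micronutrient-powder target: children 6-23 months not already covered
    by the complementary-food entitlement, floored at zero."""
    if children_6_23m < 0 or cf_recipients < 0:
        raise InvalidInputError("counts must be >= 0")
    return max(children_6_23m - cf_recipients, 0.0)


def diarrhoea_treatment_target(children_2_59m: float) -> float:
    """ORS + therapeutic zinc target.

    Every child 2-59 months is in the target; the assumed three diarrhoea
    episodes per child-year (two ORS sachets and 14 zinc days per episode)
    are folded into the annualized unit cost, not the target count.
    """
    if children_2_59m < 0:
        raise InvalidInputError("children_2_59m must be >= 0")
    return children_2_59m


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise InvalidInputError(f"{name}={value} outside [0, 1]")
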