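"""Synthetic census-style inputs and the packaged India 2014 fixture.

Two jobs live here.

1. A seeded generator of :class:`~nutricost.demographics.RegionDemographics`
   tables with the statistical structure the engine assumes (age pyramid,
   vital rates, anthropometric prevalences with severe <= moderate, a
   government-employment share and an endemic flag), so every stage of the
   pipeline is testable without any external download.

2. The packaged "India 2014" fixture.  The original national analysis prints
   intervention costs and unit costs but not its target populations; because
   cost = unit cost x target population, each target is recoverable as
   ``cost / annual unit cost``.  :func:`back_derive_target_populations` does
   that inversion, and :func:`india_2014_fixture` assembles the back-derived
   national targets, the cohort overrides, and the 35 state/union-territory
   records carrying the published five-category state cost anchors.

Fixture values are never silently mixed with formula-derived ones: cohort
overrides always win where present, and :func:`reconcile` reports the
formula-vs-fixture discrepancies instead of averaging them away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .costing import CostReport
from .demographics import (
    CohortTable,
    RegionDemographics,
    build_cohorts,
)
from .errors import InvalidInputError
from .scenarios import Scenario, packaged_scenario, run_scenario, _data_path
from .unit_costs import effective_annual_usd
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "GeneratorParams",
    "IndiaFixture",
    "back_derive_target_populations",
    "fixture_targets",
    "generate_regions",
    "india_2014_fixture",
    "india_like_params",
    "national_cost_anchors",
    "reconcile",
    "run_fixture_scenario",
    "state_cost_anchors",
]

# Published worked-example inputs for the supplementary-food sensitivity
# cross-estimates: the two packages' stated child food-supplement targets and
# the two per-child annual rates compared in the source analysis.
SUPPLEMENTATION_TARGET_SUN = 32.2e6  # children 6-23m, WHZ<-2 doubled
SUPPLEMENTATION_TARGET_INDIA_PLUS = 57.9e6  # all children 6-36m
ICDS_ANNUAL_RATE_USD = 29.0  # ICDS norm, ~$0.097/day x 300 days
SUN_CF_ANNUAL_RATE_USD = 51.10  # ready-to-use food, $0.13/day

#: India 2011 census total population (persons), the projection base year.
CENSUS_2011_POPULATION = 1210.85e6
FIXTURE_TARGET_YEAR = 2014
FIXTURE_BASE_YEAR = 2011

_BAND_WIDTH = 5.0
_N_BANDS = 20
_PYRAMID_RATIO = 0.9  # geometric decline per 5-year band, India-like pyramid
_MALE_FRACTION = 0.517


class GeneratorParams(BaseModel):
    """Sampling ranges for the synthetic region generator.

    Defaults (see :func:`india_like_params`) emulate the spread of Indian
    states: totals from ~0.1 to 200 million, crude birth rates 14-28 per
    1000, growth 0.5-2.5%/yr, and child-anthropometry prevalence ranges in
    the band reported by national surveys.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_regions: int = 10
    population_range: Tuple[float, float] = (0.1e6, 200e6)
    cbr_range: Tuple[float, float] = (14.0, 28.0)
    growth_range: Tuple[float, float] = (0.005, 0.025)
    prevalence_ranges: Dict[str, Tuple[float, float]] = {
        "whz_lt_m2": (0.08, 0.28),
        "whz_lt_m3": (0.02, 0.10),
        "waz_lt_m3": (0.05, 0.18),
    }
    frac_govt_range: Tuple[float, float] = (0.0, 0.08)
    endemic_probability: float = 0.34

    @model_validator(mode="after")
    def _check(self) -> "GeneratorParams":
        if self.n_regions < 0:
            raise InvalidInputError("n_regions must be >= 0")
        ranges = {
            "population_range": self.population_range,
            "cbr_range": self.cbr_range,
            "growth_range": self.growth_range,
            "frac_govt_range": self.frac_govt_range,
            **{f"prevalence_ranges[{k}]": v for k, v in self.prevalence_ranges.items()},
        }
        for name, (lo, hi) in ranges.items():
            if hi < lo:
                raise InvalidInputError(f"{name} is not well-ordered: ({lo}, {hi})")
        for key in ("whz_lt_m2", "whz_lt_m3", "waz_lt_m3"):
            if key not in self.prevalence_ranges:
                raise InvalidInputError(f"prevalence_ranges missing {key!r}")
            lo, hi = self.prevalence_ranges[key]
            if not (0 <= lo <= hi <= 1):
                raise InvalidInputError(f"prevalence_ranges[{key}] outside [0, 1]")
        if not 0 <= self.endemic_probability <= 1:
            raise InvalidInputError("endemic_probability outside [0, 1]")
        if self.population_range[0] < 0 or self.cbr_range[0] < 0:
            raise InvalidInputError("population and CBR ranges must be >= 0")
        if self.growth_range[0] <= -1:
            raise InvalidInputError("growth_range must stay above -1")
        return self


def india_like_params(seed: int = 0, n_regions: int = 35) -> GeneratorParams:
    """Generator parameters emulating the spread of Indian states/UTs."""
    return GeneratorParams(seed=seed, n_regions=n_regions)


def _pyramid_weights() -> np.ndarray:
    weights = _PYRAMID_RATIO ** np.arange(_N_BANDS)
    return weights / weights.sum()


def _banded_population(total: float) -> Dict[Tuple[float, float, str], float]:
    """Split ``total`` into 5-year x sex bands on the standard pyramid."""
    bands: Dict[Tuple[float, float, str], float] = {}
    for i, weight in enumerate(_pyramid_weights()):
        lo, hi = i * _BAND_WIDTH, (i + 1) * _BAND_WIDTH
        bands[(lo, hi, "m")] = total * weight * _MALE_FRACTION
        bands[(lo, hi, "f")] = total * weight * (1.0 - _MALE_FRACTION)
    return bands


def generate_regions(params: GeneratorParams) -> List[RegionDemographics]:
    """Draw ``params.n_regions`` synthetic regions, deterministically in seed.

    Prevalences are uniform within their ranges; severe wasting is redrawn
    (rejection) until it does not exceed wasting, so every output satisfies
    the full demographic invariant set.
    """
    rng = np.random.default_rng(params.seed)
    regions = []
    for i in range(params.n_regions):
        total = rng.uniform(*params.population_range)
        whz_m2 = rng.uniform(*params.prevalence_ranges["whz_lt_m2"])
        whz_m3 = rng.uniform(*params.prevalence_ranges["whz_lt_m3"])
        while whz_m3 > whz_m2:
            whz_m3 = rng.uniform(*params.prevalence_ranges["whz_lt_m3"])
        regions.append(
            RegionDemographics(
                region_id=f"synthetic_{i:03d}",
                base_year=FIXTURE_BASE_YEAR,
                population_by_band=_banded_population(total),
                crude_birth_rate=rng.uniform(*params.cbr_range),
                growth_rate=rng.uniform(*params.growth_range),
                prev_whz_lt_m3=whz_m3,
                prev_whz_lt_m2=whz_m2,
                prev_waz_lt_m3=rng.uniform(*params.prevalence_ranges["waz_lt_m3"]),
                frac_women_govt=rng.uniform(*params.frac_govt_range),
                malaria_endemic=bool(rng.random() < params.endemic_probability),
            )
        )
    return regions


def back_derive_target_populations(
    printed_costs: Mapping[str, float],
    unit_costs: Mapping[str, float],
) -> Dict[str, float]:
    """Invert cost = UC x TP: ``TP = cost(US$M) x 1e6 / annual UC (US$)``.

    Forward-costing the result reproduces the printed costs exactly (to
    floating precision), which is the fixture's round-trip identity.
    """
    targets: Dict[str, float] = {}
    for intervention_id, cost in printed_costs.items():
        if cost < 0:
            raise InvalidInputError(f"{intervention_id}: negative cost {cost}")
        unit_cost = unit_costs[intervention_id]
        if unit_cost <= 0:
            raise InvalidInputError(
                f"{intervention_id}: unit cost must be > 0, got {unit_cost}"
            )
        targets[intervention_id] = cost * 1e6 / unit_cost
    return targets


def national_cost_anchors(scenario_name: Optional[str] = None) -> pd.DataFrame:
    """The packaged national printed-cost table (US$ million per line)."""
    frame = pd.read_csv(_data_path("india_2014_costs.csv"))
    if scenario_name is not None:
        frame = frame[frame["scenario"] == scenario_name].reset_index(drop=True)
    return frame


def state_cost_anchors(include_subtotals: bool = False) -> pd.DataFrame:
    """The packaged state-level category cost anchors (US$ million).

    The source analysis prints state costs only at five-category resolution,
    so state fixtures carry category anchors, not intervention lines.
    """
    frame = pd.read_csv(_data_path("india_2014_states.csv"))
    if not include_subtotals:
        frame = frame[~frame["is_subtotal"]].reset_index(drop=True)
    return frame


def fixture_targets(scenario: Scenario) -> Dict[str, float]:
    """Back-derived national target populations for a packaged scenario."""
    anchors = national_cost_anchors(scenario.name)
    printed = dict(zip(anchors["intervention_id"], anchors["cost_usd_million"]))
    unit_costs = {
        iv.id: effective_annual_usd(iv.unit_cost, scenario.currency_ctx)
        for iv in scenario.interventions
        if iv.id in printed
    }
    return back_derive_target_populations(printed, unit_costs)


def run_fixture_scenario(name: str) -> CostReport:
    """Forward-cost a packaged scenario on its back-derived national fixture."""
    scenario = packaged_scenario(name)
    return run_scenario(scenario, fixture_targets(scenario))


def india_2014_cohort_overrides() -> Dict[str, float]:
    """National cohort sizes recovered from the printed cost lines.

    Each value is a published cost divided by its annual unit cost; the
    supplementation target (children 6-36 months) is the analysis's own
    stated 57.9 million.  Where the two packages imply different values for
    the same cohort (e.g. children 12-59 months), the locally-costed
    package's value is kept here and the discrepancy is left to
    :func:`reconcile`.
    """
    ip = national_cost_anchors("india_plus").set_index("intervention_id")[
        "cost_usd_million"
    ]
    sun = national_cost_anchors("sun").set_index("intervention_id")[
        "cost_usd_million"
    ]
    births = sun["ifa_pregnant_sun"] * 1e6 / 2.00
    return {
        "general_population": sun["salt_iodization"] * 1e6 / 0.05,
        "pregnant_women": births,
        "lactating_mothers_0_6m": births,
        "children_6_59m": ip["iron_supplements_children"] * 1e6 / 0.37,
        "children_2_59m": ip["ors_zinc"] * 1e6 / 0.64,
        "children_12_59m": ip["deworming_children"] * 1e6 / 0.23,
        "children_0_59m": sun["bcc"] * 1e6 / 7.50,
        "adolescents_11_18y": ip["ifa_deworming_adolescents"] * 1e6 / 0.40,
        "children_6_36m": SUPPLEMENTATION_TARGET_INDIA_PLUS,
    }


def _national_demographics(overrides: Mapping[str, float]) -> RegionDemographics:
    """All-India region whose projection reproduces the fixture aggregates.

    The growth rate is calibrated so the 2011 census base projects to the
    back-derived 2014 population, and the CBR so projected births equal the
    back-derived pregnancy cohort.
    """
    pop_2014 = overrides["general_population"]
    births = overrides["pregnant_women"]
    elapsed = FIXTURE_TARGET_YEAR - FIXTURE_BASE_YEAR
    growth = (pop_2014 / CENSUS_2011_POPULATION) ** (1.0 / elapsed) - 1.0
    cbr = births / pop_2014 * 1000.0
    children_6_59m = overrides["children_6_59m"]
    ip = national_cost_anchors("india_plus").set_index("intervention_id")[
        "cost_usd_million"
    ]
    treated = ip["sam_treatment"] * 1e6 / 107.38
    prev_whz_m3 = treated / (children_6_59m * 2.0 * 0.15)
    prev_waz_m3 = (ip["food_rations_sam"] * 1e6 / 13.06) / children_6_59m
    frac_govt = 1.0 - (ip["cash_transfers"] * 1e6 / 103.22) / births
    return RegionDemographics(
        region_id="india",
        base_year=FIXTURE_BASE_YEAR,
        population_by_band=_banded_population(CENSUS_2011_POPULATION),
        crude_birth_rate=cbr,
        growth_rate=growth,
        prev_whz_lt_m3=prev_whz_m3,
        prev_whz_lt_m2=0.20,  # national-survey wasting level; not back-derivable
        prev_waz_lt_m3=prev_waz_m3,
        frac_women_govt=frac_govt,
        malaria_endemic=False,
    )


@dataclass
class IndiaFixture:
    """The packaged India 2014 inputs.

    ``national`` is the calibrated all-India region; ``states`` are the 35
    state/union-territory records (census-pyramid shape scaled to published
    totals, national vital rates and prevalences, endemic flags); cohort
    ``overrides`` are the back-derived national cohorts;
    ``state_anchors``/``group_anchors`` carry the published five-category
    state costs and regional subtotals in US$ million.
    """

    national: RegionDemographics
    states: List[RegionDemographics]
    overrides: Dict[str, float]
    state_anchors: pd.DataFrame
    group_anchors: pd.DataFrame


def india_2014_fixture() -> IndiaFixture:
    """Assemble the packaged national + state fixture."""
    overrides = india_2014_cohort_overrides()
    national = _national_demographics(overrides)
    anchors = state_cost_anchors(include_subtotals=True)
    states_frame = anchors[~anchors["is_subtotal"]].reset_index(drop=True)
    groups_frame = anchors[anchors["is_subtotal"]].reset_index(drop=True)
    states = [
        RegionDemographics(
            region_id=row["region_id"],
            base_year=FIXTURE_TARGET_YEAR,
            population_by_band=_banded_population(
                row["total_population_million"] * 1e6
            ),
            crude_birth_rate=national.crude_birth_rate,
            growth_rate=national.growth_rate,
            prev_whz_lt_m3=national.prev_whz_lt_m3,
            prev_whz_lt_m2=national.prev_whz_lt_m2,
            prev_waz_lt_m3=national.prev_waz_lt_m3,
            frac_women_govt=national.frac_women_govt,
            malaria_endemic=bool(row["malaria_endemic"]),
        )
        for _idx, row in states_frame.iterrows()
    ]
    return IndiaFixture(
        national=national,
        states=states,
        overrides=overrides,
        state_anchors=states_frame,
        group_anchors=groups_frame,
    )


def national_cohorts(target_year: int = FIXTURE_TARGET_YEAR) -> CohortTable:
    """Fixture national cohort table: projection formulas with the
    back-derived overrides applied on top."""
    fixture = india_2014_fixture()
    return build_cohorts(
        fixture.national, target_year, overrides=fixture.overrides
    )


def reconcile(scenario_name: str = "india_plus") -> pd.DataFrame:
    """Formula-vs-fixture reconciliation report.

    For every back-derived national target population, shows the value the
    stationary projection formulas would give for the underlying cohort,
    the fixture value, and their ratio.  Discrepancies (e.g. the two
    packages' mutually inconsistent deworming cohorts) are surfaced here
    rather than averaged.
    """
    fixture = india_2014_fixture()
    formula = build_cohorts(fixture.national, FIXTURE_TARGET_YEAR).cohorts
    scenario = packaged_scenario(scenario_name)
    targets = fixture_targets(scenario)
    rows = []
    for iv in scenario.interventions:
        cohort = iv.target_rule.cohort
        rows.append(
            {
                "intervention": iv.id,
                "cohort": cohort,
                "formula_cohort": formula.get(cohort),
                "fixture_target": targets[iv.id],
                "ratio_fixture_to_formula": (
                    targets[iv.id] / formula[cohort]
                    if formula.get(cohort)
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
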