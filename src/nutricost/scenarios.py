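"""Scenario definition, execution, comparison and one-way sensitivity swaps.

A scenario is a declarative package of interventions: the ten-intervention
Scaling Up Nutrition (SUN) global costing package and the fifteen-intervention
*India Plus* package drawn from India's national policy framework ship with
the package as TOML configs (``data/sun.toml``, ``data/india_plus.toml``).
The SUN/India Plus differences — choice of intervention, target group and
unit cost — are therefore expressed purely as data.

Config layout::

    [scenario]            # name, description
    [currency]            # inr_per_usd, inflation_factor
    [unit_costs.<id>]     # one registry entry per unit-cost expression
    [intervention.<id>]   # name, category, unit_cost = "<registry id>",
                          # coverage, and a [intervention.<id>.target] table
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from .costing import CostReport, Intervention, compute_cost_line
from .demographics import RegionDemographics, build_cohorts
from .errors import ConfigurationError, ResolutionError, SchemaError
from .target_populations import TargetRule, resolve_all
from .unit_costs import CurrencyContext, UnitCost

__all__ = [
    "Scenario",
    "compare_scenarios",
    "load_scenario",
    "packaged_scenario",
    "run_scenario",
    "sensitivity_swap",
]

PACKAGED_SCENARIOS = ("sun", "india_plus")


class Scenario(BaseModel):
    """A named, fully resolved intervention package."""

    model_config = ConfigDict(frozen=True)

    name: str
    description: str = ""
    interventions: List[Intervention]
    currency_ctx: CurrencyContext = CurrencyContext()

    def intervention(self, intervention_id: str) -> Intervention:
        for iv in self.interventions:
            if iv.id == intervention_id:
                return iv
        raise ResolutionError(
            f"intervention {intervention_id!r} not in scenario {self.name!r}"
        )

    @property
    def rules(self) -> Dict[str, TargetRule]:
        return {iv.id: iv.target_rule for iv in self.interventions}


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("nutricost.data").joinpath(filename)))


def packaged_scenario(name: str) -> Scenario:
    """Load one of the packaged scenario configs by short name."""
    if name not in PACKAGED_SCENARIOS:
        raise SchemaError(
            f"unknown packaged scenario {name!r}; available: {PACKAGED_SCENARIOS}"
        )
    return load_scenario(_data_path(f"{name}.toml"))


def load_scenario(path: str | Path) -> Scenario:
    """Parse and validate a scenario config file.

    Raises :class:`SchemaError` naming the offending section and fields on
    any validation failure.
    """
    path = Path(path)
    try:
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
    except tomllib.TOMLDecodeError as exc:
        raise SchemaError(f"{path}: not valid TOML: {exc}") from exc

    for section in ("scenario", "intervention"):
        if section not in raw:
            raise SchemaError(f"{path}: missing [{section}] section")
    meta = raw["scenario"]
    if "name" not in meta:
        raise SchemaError(f"{path}: [scenario] must declare a name")

    try:
        ctx = CurrencyContext(**raw.get("currency", {}))
    except (ValidationError, ValueError) as exc:
        raise SchemaError(f"{path}: [currency]: {exc}") from exc

    registry: Dict[str, UnitCost] = {}
    for uc_id, spec in raw.get("unit_costs", {}).items():
        try:
            registry[uc_id] = UnitCost(**spec)
        except (ValidationError, ConfigurationError, ValueError) as exc:
            raise SchemaError(f"{path}: [unit_costs.{uc_id}]: {exc}") from exc

    interventions: List[Intervention] = []
    seen = set()
    for iv_id, spec in raw["intervention"].items():
        if iv_id in seen:
            raise SchemaError(f"{path}: duplicate intervention id {iv_id!r}")
        seen.add(iv_id)
        spec = dict(spec)
        uc_ref = spec.pop("unit_cost", None)
        if uc_ref is None or uc_ref not in registry:
            raise SchemaError(
                f"{path}: [intervention.{iv_id}]: unit_cost must reference a "
                f"[unit_costs.*] entry, got {uc_ref!r}"
            )
        target_spec = spec.pop("target", None)
        if target_spec is None:
            raise SchemaError(
                f"{path}: [intervention.{iv_id}]: missing [target] table"
            )
        try:
            rule = TargetRule(**target_spec)
            interventions.append(
                Intervention(
                    id=iv_id,
                    target_rule=rule,
                    unit_cost=registry[uc_ref],
                    **spec,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise SchemaError(f"{path}: [intervention.{iv_id}]: {exc}") from exc

    if not interventions:
        raise SchemaError(f"{path}: scenario declares no interventions")
    for iv in interventions:
        if iv.target_rule.subtract_rule is not None and iv.target_rule.subtract_rule not in seen:
            raise SchemaError(
                f"{path}: [intervention.{iv.id}]: subtract_rule "
                f"{iv.target_rule.subtract_rule!r} is not an intervention id"
            )
    return Scenario(
        name=str(meta["name"]),
        description=str(meta.get("description", "")),
        interventions=interventions,
        currency_ctx=ctx,
    )


def run_scenario(
    scenario: Scenario,
    targets: Mapping[str, float],
    region_id: str = "national",
) -> CostReport:
    """Cost every intervention against pre-resolved target populations.

    ``targets`` maps intervention id to beneficiaries (e.g. fixture
    back-derived counts, or the output of rule resolution on a region).
    """
    report = CostReport(scenario=scenario.name)
    for iv in scenario.interventions:
        if iv.id not in targets:
            raise ResolutionError(
                f"no target population for intervention {iv.id!r}"
            )
        report.lines.append(
            compute_cost_line(iv, targets[iv.id], scenario.currency_ctx, region_id)
        )
    return report


def run_on_regions(
    scenario: Scenario,
    regions: List[RegionDemographics],
    target_year: int = 2014,
    cohort_overrides: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> CostReport:
    """Cost a scenario over regions by resolving its target rules.

    Cohorts come from the demographic projection for each region;
    ``cohort_overrides`` (region id -> cohort name -> persons) replace
    formula values where a region has back-derived fixture cohorts.
    """
    report = CostReport(scenario=scenario.name)
    rules = scenario.rules
    for demo in regions:
        overrides = (cohort_overrides or {}).get(demo.region_id)
        cohorts = build_cohorts(demo, target_year, overrides=overrides)
        targets = resolve_all(rules, cohorts, demo)
        for iv in scenario.interventions:
            report.lines.append(
                compute_cost_line(
                    iv, targets[iv.id], scenario.currency_ctx, demo.region_id
                )
            )
    return report


def compare_scenarios(
    a: CostReport, b: CostReport, level: str = "category"
) -> pd.DataFrame:
    """Side-by-side group totals with the difference ``b - a`` (US$ million)."""
    agg_a = a.aggregate(level)
    agg_b = b.aggregate(level)
    groups = sorted(set(agg_a) | set(agg_b))
    frame = pd.DataFrame(
        {
            a.scenario: [agg_a.get(g, 0.0) for g in groups],
            b.scenario: [agg_b.get(g, 0.0) for g in groups],
        },
        index=pd.Index(groups, name=level),
    )
    frame["difference"] = frame[b.scenario] - frame[a.scenario]
    total = frame.sum(axis=0).to_frame().T
    total.index = pd.Index(["total"], name=level)
    return pd.concat([frame, total])


def sensitivity_swap(
    scenario: Scenario,
    targets: Mapping[str, float],
    intervention_id: str,
    *,
    new_unit_cost: Optional[UnitCost] = None,
    new_target: Optional[float] = None,
    region_id: str = "national",
) -> CostReport:
    """One-way sensitivity analysis: replace one intervention's unit cost
    and/or target population, recompute only that line.

    All other lines are bit-identical to the baseline run.
    """
    if new_unit_cost is None and new_target is None:
        raise ConfigurationError(
            "sensitivity_swap needs a replacement unit cost or target"
        )
    scenario.intervention(intervention_id)  # raises on unknown id
    report = CostReport(scenario=scenario.name)
    for iv in scenario.interventions:
        target = targets[iv.id]
        if iv.id == intervention_id:
            if new_unit_cost is not None:
                iv = iv.model_copy(update={"unit_cost": new_unit_cost})
            if new_target is not None:
                target = new_target
        report.lines.append(
            compute_cost_line(iv, target, scenario.currency_ctx, region_id)
        )
    return report
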