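"""Core costing engine: cost = unit cost x target population x coverage.

A :class:`CostLine` is one intervention in one region; a :class:`CostReport`
collects lines for a scenario and provides exact aggregation by intervention,
category, region or scenario, percentage shares, and the per-child package
summary.  All arithmetic is carried at full floating precision; the half-up
rounding to 0.01 US$ million happens only at the reporting surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Literal, Mapping, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigurationError, InvalidInputError, UndefinedShareError
from .target_populations import TargetRule
from .unit_costs import (
    CurrencyContext,
    UnitCost,
    effective_annual_usd,
    round_money,
)

__all__ = [
    "CATEGORIES",
    "CostLine",
    "CostReport",
    "Intervention",
    "aggregate",
    "compute_cost_line",
    "compute_shares",
    "per_child_package_cost",
]

Category = Literal[
    "counselling",
    "supplementation",
    "micronutrient_deworming",
    "health",
    "fortification",
    "cash_transfer",
    "bcc",
]
CATEGORIES: Tuple[str, ...] = (
    "counselling",
    "supplementation",
    "micronutrient_deworming",
    "health",
    "fortification",
    "cash_transfer",
    "bcc",
)

GroupBy = Literal["intervention", "category", "region", "scenario"]
ShareLevel = Literal["intervention", "category"]


class Intervention(BaseModel):
    """One costed intervention: identity, eligibility rule, unit cost,
    coverage fraction (1.0 = full coverage of the target population)."""

    model_config = ConfigDict(frozen=True)

    id: str
    name: str
    category: Category
    target_rule: TargetRule
    unit_cost: UnitCost
    coverage: float = Field(default=1.0, ge=0, le=1)


@dataclass(frozen=True)
class CostLine:
    """One intervention x region cost: US$ million per year at the given
    coverage.  ``cost`` always equals
    ``target_population * coverage * annual_unit_cost / 1e6``."""

    intervention_id: str
    category: str
    region_id: str
    target_population: float
    annual_unit_cost: float  # US$ per beneficiary per year
    coverage: float
    cost: float  # US$ million per year


@dataclass
class CostReport:
    """A scenario's cost lines plus derived aggregates and shares."""

    scenario: str
    lines: List[CostLine] = field(default_factory=list)

    @property
    def total(self) -> float:
        """Grand total in US$ million per year (unrounded)."""
        return sum(line.cost for line in self.lines)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "intervention": line.intervention_id,
                    "category": line.category,
                    "region": line.region_id,
                    "target_population": line.target_population,
                    "unit_cost_usd_yr": line.annual_unit_cost,
                    "coverage": line.coverage,
                    "cost_usd_million": line.cost,
                }
                for line in self.lines
            ]
        )
        return frame

    def aggregate(self, by: GroupBy) -> Dict[str, float]:
        return aggregate(self, by)

    def shares(self, level: ShareLevel = "intervention") -> Dict[str, float]:
        return compute_shares(self, level)

    def line(self, intervention_id: str, region_id: str | None = None) -> CostLine:
        matches = [
            l
            for l in self.lines
            if l.intervention_id == intervention_id
            and (region_id is None or l.region_id == region_id)
        ]
        if not matches:
            raise KeyError(intervention_id)
        if len(matches) > 1:
            raise KeyError(
                f"{intervention_id!r} matches {len(matches)} lines; pass region_id"
            )
        return matches[0]


def compute_cost_line(
    iv: Intervention,
    target_population: float,
    ctx: CurrencyContext,
    region_id: str = "national",
) -> CostLine:
    """Cost one intervention for one region's resolved target population."""
    if target_population < 0:
        raise InvalidInputError(
            f"target_population must be >= 0, got {target_population}"
        )
    try:
        annual = effective_annual_usd(iv.unit_cost, ctx)
    except ConfigurationError as exc:
        raise ConfigurationError(f"intervention {iv.id!r}: {exc}") from exc
    return CostLine(
        intervention_id=iv.id,
        category=iv.category,
        region_id=region_id,
        target_population=target_population,
        annual_unit_cost=annual,
        coverage=iv.coverage,
        cost=target_population * iv.coverage * annual / 1e6,
    )


_GROUP_KEY = {
    "intervention": lambda line: line.intervention_id,
    "category": lambda line: line.category,
    "region": lambda line: line.region_id,
}


def aggregate(report: CostReport, by: GroupBy) -> Dict[str, float]:
    """Exact sums of line costs per group, in US$ million per year."""
    if not report.lines:
        raise InvalidInputError("cannot aggregate an empty report")
    if by == "scenario":
        return {report.scenario: report.total}
    try:
        key = _GROUP_KEY[by]
    except KeyError:
        raise InvalidInputError(f"unknown grouping key {by!r}") from None
    sums: Dict[str, float] = {}
    for line in report.lines:
        sums[key(line)] = sums.get(key(line), 0.0) + line.cost
    return sums


def compute_shares(report: CostReport, level: ShareLevel) -> Dict[str, float]:
    """Percentage share of the grand total per group, to 2 decimals."""
    total = report.total
    if total <= 0:
        raise UndefinedShareError("shares undefined: grand total is zero")
    return {
        group: round_money(100.0 * cost / total, 2)
        for group, cost in aggregate(report, level).items()
    }


def per_child_package_cost(component_costs: Mapping[str, float]) -> float:
    """Average package cost per child 0-24 months per year: the sum of the
    per-child component costs (US$/child-year)."""
    for name, value in component_costs.items():
        if value < 0:
            raise InvalidInputError(f"component {name!r} is negative ({value})")
    return float(sum(component_costs.values()))


def rescale_lines(lines: Iterable[CostLine], factor: float) -> List[CostLine]:
    """Scale every line's unit cost (and hence cost) by ``factor``; used by
    linearity checks and currency rescaling."""
    return [
        replace(
            line,
            annual_unit_cost=line.annual_unit_cost * factor,
            cost=line.cost * factor,
        )
        for line in lines
    ]
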