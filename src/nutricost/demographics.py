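"""Demographic projection and cohort derivation.

Costing starts from census-style inputs: a base-year population broken into
age bands by sex, a crude birth rate (CBR) and an average annual growth rate.
This module projects the base population to the target year with compound
growth, derives an annual birth cohort from the CBR, and slices both into the
named beneficiary cohorts the intervention rules refer to (children 6-36
months, adolescents 11-18 years, pregnant women, ...).

Child cohorts use a stationary-population approximation: a cohort spanning
``m`` months of age contains ``births_per_year * m / 12`` children, with no
under-five mortality adjustment.  Adolescent cohorts come from the age-band
table with uniform interpolation inside bands.  Both are deliberate
simplifications — see docs/methods.md — and any cohort may be overridden by
a fixture value where a published back-derived count exists.

Age conventions are half-open ``[lo, hi)`` everywhere: "children 6-23 months"
is the interval [6, 24) months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .errors import CoverageError, InvalidInputError, InvalidIntervalError, SchemaError

__all__ = [
    "AGE_COHORT_MONTHS",
    "COHORT_NAMES",
    "CohortTable",
    "RegionDemographics",
    "age_cohort_size",
    "annual_births",
    "build_cohorts",
    "cohort_from_age_bands",
    "project_population",
    "read_regions_csv",
    "write_regions_csv",
]

#: Birth-cohort age windows in months, half-open [lo, hi).
AGE_COHORT_MONTHS: Dict[str, Tuple[float, float]] = {
    "children_0_6m": (0, 6),
    "children_6_12m": (6, 12),
    "children_6_23m": (6, 24),
    "children_2_59m": (2, 60),
    "children_6_36m": (6, 36),
    "children_6_59m": (6, 60),
    "children_12_59m": (12, 60),
    "children_0_59m": (0, 60),
}

COHORT_NAMES: Tuple[str, ...] = tuple(AGE_COHORT_MONTHS) + (
    "adolescents_11_18y",
    "pregnant_women",
    "lactating_mothers_0_6m",
    "households_with_u5",
    "general_population",
)

_SEXES = ("m", "f")

#: Fields of the region CSV schema besides the age-band columns.
_SCALAR_COLUMNS = (
    "region_id",
    "base_year",
    "crude_birth_rate",
    "growth_rate",
    "prev_whz_lt_m3",
    "prev_whz_lt_m2",
    "prev_waz_lt_m3",
    "frac_women_govt",
    "malaria_endemic",
)


@dataclass
class RegionDemographics:
    """Census-style inputs for one region.

    ``population_by_band`` maps ``(lo_years, hi_years, sex)`` with sex in
    ``{"m", "f"}`` to persons; the (lo, hi) bands must be non-overlapping and
    jointly cover [0, 100) years.  Prevalences are fractions of children
    under five below the stated anthropometric threshold; ``frac_women_govt``
    is the fraction of women 18-50 employed in the government sector (they
    are ineligible for the maternity cash transfer).
    """

    region_id: str
    base_year: int
    population_by_band: Dict[Tuple[float, float, str], float]
    crude_birth_rate: float  # births per 1000 persons per year
    growth_rate: float  # fraction per year
    prev_whz_lt_m3: float
    prev_whz_lt_m2: float
    prev_waz_lt_m3: float
    frac_women_govt: float
    malaria_endemic: bool = False

    def __post_init__(self) -> None:
        for key, value in self.population_by_band.items():
            if value < 0:
                raise InvalidInputError(
                    f"{self.region_id}: negative population {value} in band {key}"
                )
        for name in (
            "prev_whz_lt_m3",
            "prev_whz_lt_m2",
            "prev_waz_lt_m3",
            "frac_women_govt",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidInputError(
                    f"{self.region_id}: {name}={value} outside [0, 1]"
                )
        if self.prev_whz_lt_m3 > self.prev_whz_lt_m2:
            raise InvalidInputError(
                f"{self.region_id}: severe wasting prevalence "
                f"{self.prev_whz_lt_m3} exceeds wasting prevalence "
                f"{self.prev_whz_lt_m2}"
            )
        if self.crude_birth_rate < 0:
            raise InvalidInputError(
                f"{self.region_id}: crude_birth_rate must be >= 0"
            )
        if self.growth_rate <= -1.0:
            raise InvalidInputError(f"{self.region_id}: growth_rate must be > -1")
        self._check_band_coverage()

    def _check_band_coverage(self) -> None:
        bands = sorted({(lo, hi) for lo, hi, _sex in self.population_by_band})
        if not bands:
            raise InvalidInputError(f"{self.region_id}: empty age-band table")
        cursor = 0.0
        for lo, hi in bands:
            if hi <= lo:
                raise InvalidIntervalError(
                    f"{self.region_id}: degenerate band [{lo}, {hi})"
                )
            if not math.isclose(lo, cursor, abs_tol=1e-9):
                raise InvalidInputError(
                    f"{self.region_id}: age bands have a gap or overlap at {lo}"
                )
            cursor = hi
        if not math.isclose(bands[0][0], 0.0) or not math.isclose(cursor, 100.0):
            raise InvalidInputError(
                f"{self.region_id}: age bands must cover [0, 100), got "
                f"[{bands[0][0]}, {cursor})"
            )

    @property
    def total_population(self) -> float:
        return float(sum(self.population_by_band.values()))

    @property
    def bands(self) -> List[Tuple[float, float]]:
        """Sorted distinct (lo, hi) band edges in years."""
        return sorted({(lo, hi) for lo, hi, _sex in self.population_by_band})


@dataclass
class CohortTable:
    """Target-year sizes of the named beneficiary cohorts for one region."""

    region_id: str
    target_year: int
    cohorts: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.cohorts.items():
            if value < 0:
                raise InvalidInputError(
                    f"{self.region_id}: cohort {name} is negative ({value})"
                )

    def __getitem__(self, name: str) -> float:
        return self.cohorts[name]

    def __contains__(self, name: str) -> bool:
        return name in self.cohorts


def project_population(
    base_pop: float, growth_rate: float, elapsed_years: float
) -> float:
    """Compound-growth projection: ``base_pop * (1 + growth_rate)**elapsed``."""
    if base_pop < 0:
        raise InvalidInputError(f"base_pop must be >= 0, got {base_pop}")
    if growth_rate <= -1.0:
        raise InvalidInputError(f"growth_rate must be > -1, got {growth_rate}")
    if elapsed_years < 0:
        raise InvalidInputError(f"elapsed_years must be >= 0, got {elapsed_years}")
    return base_pop * (1.0 + growth_rate) ** elapsed_years


def annual_births(population: float, cbr: float) -> float:
    """Births per year from a crude birth rate in births/1000 persons/yr."""
    if population < 0:
        raise InvalidInputError(f"population must be >= 0, got {population}")
    if cbr < 0:
        raise InvalidInputError(f"crude birth rate must be >= 0, got {cbr}")
    return population * cbr / 1000.0


def age_cohort_size(
    births_per_year: float, lo_months: float, hi_months: float
) -> float:
    """Stationary-population size of the age window [lo, hi) months.

    Each month of age holds one-twelfth of an annual birth cohort; no
    mortality thinning is applied.
    """
    if births_per_year < 0:
        raise InvalidInputError(
            f"births_per_year must be >= 0, got {births_per_year}"
        )
    if lo_months < 0 or hi_months <= lo_months:
        raise InvalidIntervalError(
            f"invalid age window [{lo_months}, {hi_months}) months"
        )
    return births_per_year * (hi_months - lo_months) / 12.0


def cohort_from_age_bands(
    population_by_band: Mapping[Tuple[float, float, str], float],
    lo_years: float,
    hi_years: float,
) -> float:
    """Persons aged [lo, hi) years from a banded table, both sexes.

    Full bands inside the window contribute entirely; bands straddling an
    edge contribute the uniformly interpolated fraction of their width.
    """
    if hi_years <= lo_years:
        raise InvalidIntervalError(f"invalid age range [{lo_years}, {hi_years})")
    band_edges = sorted({(lo, hi) for lo, hi, _sex in population_by_band})
    if not band_edges:
        raise CoverageError("empty age-band table")
    min_lo = band_edges[0][0]
    max_hi = max(hi for _lo, hi in band_edges)
    if lo_years < min_lo - 1e-9 or hi_years > max_hi + 1e-9:
        raise CoverageError(
            f"requested range [{lo_years}, {hi_years}) outside band coverage "
            f"[{min_lo}, {max_hi})"
        )
    total = 0.0
    for (lo, hi, _sex), persons in population_by_band.items():
        overlap = min(hi, hi_years) - max(lo, lo_years)
        if overlap > 0:
            total += persons * overlap / (hi - lo)
    return total


def build_cohorts(
    demo: RegionDemographics,
    target_year: int,
    *,
    pregnancy_multiplier: float = 1.0,
    children_per_household: float = 2.0,
    overrides: Optional[Mapping[str, float]] = None,
) -> CohortTable:
    """Project ``demo`` to ``target_year`` and derive every named cohort.

    The pregnant-women cohort is ``annual_births * pregnancy_multiplier``
    (no pregnancy-loss adjustment by default).  Lactating mothers 0-6 months
    post-delivery are counted as annualized beneficiaries — every birth in
    the year starts one 6-month benefit spell — so the cohort equals annual
    births.  Households with an under-five child assume
    ``children_per_household`` under-fives per household (programme norm: 2).

    ``overrides`` replace formula-derived values wherever present; published
    back-derived fixture cohorts always take precedence over the stationary
    approximation.
    """
    if target_year < demo.base_year:
        raise InvalidInputError(
            f"target_year {target_year} precedes base_year {demo.base_year}"
        )
    if pregnancy_multiplier < 0:
        raise InvalidInputError("pregnancy_multiplier must be >= 0")
    if children_per_household <= 0:
        raise InvalidInputError("children_per_household must be > 0")

    elapsed = target_year - demo.base_year
    scale = (1.0 + demo.growth_rate) ** elapsed
    pop_target = project_population(demo.total_population, demo.growth_rate, elapsed)
    births = annual_births(pop_target, demo.crude_birth_rate)

    cohorts: Dict[str, float] = {}
    for name, (lo_m, hi_m) in AGE_COHORT_MONTHS.items():
        cohorts[name] = age_cohort_size(births, lo_m, hi_m)
    # Adolescents come from the age-band table (they were born well before the
    # target year), scaled by the same compound growth as the total.
    cohorts["adolescents_11_18y"] = (
        cohort_from_age_bands(demo.population_by_band, 11.0, 18.0) * scale
    )
    cohorts["pregnant_women"] = births * pregnancy_multiplier
    cohorts["lactating_mothers_0_6m"] = births
    cohorts["households_with_u5"] = cohorts["children_0_59m"] / children_per_household
    cohorts["general_population"] = pop_target

    if overrides:
        for name, value in overrides.items():
            if value < 0:
                raise InvalidInputError(f"override {name} is negative ({value})")
            cohorts[name] = float(value)
    return CohortTable(demo.region_id, target_year, cohorts)


# ---------------------------------------------------------------------------
# CSV interface: one row per region; age bands as pop_m_<lo>_<hi>/pop_f_<lo>_<hi>
# columns (UTF-8, dot decimal).
# ---------------------------------------------------------------------------


def _parse_band_column(name: str) -> Optional[Tuple[str, float, float]]:
    parts = name.split("_")
    if len(parts) != 4 or parts[0] != "pop" or parts[1] not in _SEXES:
        return None
    try:
        lo, hi = float(parts[2]), float(parts[3])
    except ValueError:
        return None
    return parts[1], lo, hi


def read_regions_csv(path: str | Path) -> List[RegionDemographics]:
    """Read a region demographics table; raise :class:`SchemaError` with the
    offending coordinates on malformed input."""
    frame = pd.read_csv(path)
    if frame.empty:
        raise SchemaError(f"{path}: no region rows")
    missing = [c for c in _SCALAR_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    band_columns = {
        name: spec
        for name in frame.columns
        if (spec := _parse_band_column(name)) is not None
    }
    if not band_columns:
        raise SchemaError(f"{path}: no pop_<sex>_<lo>_<hi> age-band columns")
    if frame["region_id"].duplicated().any():
        dupes = frame.loc[frame["region_id"].duplicated(), "region_id"].tolist()
        raise SchemaError(f"{path}: duplicated region_id {dupes}")

    regions = []
    for idx, row in frame.iterrows():
        bands = {
            (lo, hi, sex): float(row[col])
            for col, (sex, lo, hi) in band_columns.items()
        }
        try:
            regions.append(
                RegionDemographics(
                    region_id=str(row["region_id"]),
                    base_year=int(row["base_year"]),
                    population_by_band=bands,
                    crude_birth_rate=float(row["crude_birth_rate"]),
                    growth_rate=float(row["growth_rate"]),
                    prev_whz_lt_m3=float(row["prev_whz_lt_m3"]),
                    prev_whz_lt_m2=float(row["prev_whz_lt_m2"]),
                    prev_waz_lt_m3=float(row["prev_waz_lt_m3"]),
                    frac_women_govt=float(row["frac_women_govt"]),
                    malaria_endemic=bool(row["malaria_endemic"]),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            raise SchemaError(f"{path}: row {idx}: {exc}") from exc
    return regions


def write_regions_csv(regions: Iterable[RegionDemographics], path: str | Path) -> None:
    """Write regions in the same schema :func:`read_regions_csv` accepts."""
    regions = list(regions)
    rows = []
    for demo in regions:
        row: Dict[str, object] = {c: getattr(demo, c) for c in _SCALAR_COLUMNS}
        row["malaria_endemic"] = bool(demo.malaria_endemic)
        for (lo, hi, sex), persons in sorted(demo.population_by_band.items()):
            row[f"pop_{sex}_{_fmt_edge(lo)}_{_fmt_edge(hi)}"] = persons
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _fmt_edge(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)
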