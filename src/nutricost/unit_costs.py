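"""Unit-cost normalization.

Programme unit costs arrive on heterogeneous bases — rupees per feeding day,
dollars per counselling visit, dollars per household-year, dollars per treated
case — and must be normalized to **US$ per beneficiary per year** before they
can be multiplied by a target population.  This module owns that
normalization, the INR→USD conversion, and the money-rounding conventions
used in reports.

Conventions
-----------
* Feeding programmes run 300 days per year for full-year entitlements,
  150 days for 6-month entitlements, and 90 days for the 3-month therapeutic
  ration; the day count is part of each :class:`UnitCost`, not a global.
* The default exchange rate is 62.0 INR/USD, calibrated so that the ICDS
  child ration norm of Rs 6/day over 300 days annualizes to $29.03 exactly.
* Reported money is rounded half-up: unit costs to the cent, cost lines to
  0.01 US$ million.  Full precision is carried internally.
* A registry entry may carry ``printed_annual_usd``, the annual per-beneficiary
  value as published in the source cost norms.  When present it is the value
  used for costing, so that published cost lines are reproduced verbatim even
  where the publication's own rounding path differs from ours by a cent.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "Basis",
    "Currency",
    "CurrencyContext",
    "UnitCost",
    "annualize",
    "annualize_reported",
    "inflation_adjust",
    "round_money",
    "to_usd",
]

Currency = Literal["INR", "USD"]
Basis = Literal[
    "per_beneficiary_year",
    "per_day",
    "per_visit",
    "per_household_year",
    "per_case",
    "per_pregnancy",
]

#: Convention field each basis requires on the UnitCost.
_REQUIRED_FIELD = {
    "per_day": "days_per_year",
    "per_visit": "visits_per_year",
    "per_household_year": "children_per_household",
}


class CurrencyContext(BaseModel):
    """Exchange-rate and inflation conventions for one costing run.

    ``inr_per_usd`` defaults to 62.0 INR/USD (the rate that reproduces the
    published annual ration values from the rupee day-norms).  No price index
    is applied by default; ``inflation_factor`` is a plain multiplier on every
    annualized cost.
    """

    model_config = ConfigDict(frozen=True)

    inr_per_usd: float = 62.0
    inflation_factor: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "CurrencyContext":
        if self.inr_per_usd <= 0:
            raise InvalidInputError(f"inr_per_usd must be > 0, got {self.inr_per_usd}")
        if self.inflation_factor <= 0:
            raise InvalidInputError(
                f"inflation_factor must be > 0, got {self.inflation_factor}"
            )
        return self


class UnitCost(BaseModel):
    """One unit-cost expression, as stated by its source programme.

    ``amount`` is on the stated ``basis`` in the stated ``currency``; the
    basis-specific convention field (days per year, visits per year, children
    per household) must be present exactly when the basis requires it.
    """

    model_config = ConfigDict(frozen=True)

    amount: float
    currency: Currency = "USD"
    basis: Basis = "per_beneficiary_year"
    days_per_year: Optional[float] = None
    visits_per_year: Optional[float] = None
    children_per_household: Optional[float] = None
    printed_annual_usd: Optional[float] = None
    source: str = ""

    @model_validator(mode="after")
    def _check(self) -> "UnitCost":
        if self.amount < 0:
            raise InvalidInputError(f"unit-cost amount must be >= 0, got {self.amount}")
        required = _REQUIRED_FIELD.get(self.basis)
        if required is not None:
            value = getattr(self, required)
            if value is None:
                raise ConfigurationError(
                    f"basis {self.basis!r} requires field {required!r}"
                )
            if value <= 0:
                raise ConfigurationError(f"{required} must be > 0, got {value}")
        return self


def round_money(amount: float, decimals: int = 2) -> float:
    """Round half-up to ``decimals`` places (reporting convention).

    Python's builtin ``round`` is banker's rounding; published cost tables
    round halves away from zero, so we go through :class:`decimal.Decimal`.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(amount)).quantize(quantum, rounding=ROUND_HALF_UP))


def to_usd(amount: float, currency: Currency, ctx: CurrencyContext) -> float:
    """Convert ``amount`` in ``currency`` to US$ under ``ctx``.

    USD passes through unchanged; INR divides by the context exchange rate.
    """
    if amount < 0:
        raise InvalidInputError(f"amount must be >= 0, got {amount}")
    if currency == "USD":
        return amount
    if currency == "INR":
        return amount / ctx.inr_per_usd
    raise InvalidInputError(f"unknown currency {currency!r}")


def inflation_adjust(amount: float, ctx: CurrencyContext) -> float:
    """Apply the context inflation factor to ``amount``."""
    if amount < 0:
        raise InvalidInputError(f"amount must be >= 0, got {amount}")
    return amount * ctx.inflation_factor


def annualize(uc: UnitCost, ctx: CurrencyContext) -> float:
    """Normalize ``uc`` to unrounded US$ per beneficiary per year.

    per_day multiplies by the entitlement's feeding days per year; per_visit
    by the visit schedule; per_household_year divides by the children per
    household (so the result is per child); per_case, per_pregnancy and
    per_beneficiary_year are already annual per-beneficiary amounts.  Currency
    conversion and the inflation factor are applied afterwards.
    """
    if uc.basis == "per_day":
        native = uc.amount * uc.days_per_year
    elif uc.basis == "per_visit":
        native = uc.amount * uc.visits_per_year
    elif uc.basis == "per_household_year":
        native = uc.amount / uc.children_per_household
    else:  # per_case, per_pregnancy, per_beneficiary_year
        native = uc.amount
    return inflation_adjust(to_usd(native, uc.currency, ctx), ctx)


def annualize_reported(uc: UnitCost, ctx: CurrencyContext) -> float:
    """:func:`annualize`, rounded to the cent for reporting."""
    return round_money(annualize(uc, ctx), 2)


def effective_annual_usd(uc: UnitCost, ctx: CurrencyContext) -> float:
    """Annual US$ per beneficiary used when costing.

    Returns the registry's published annual value when one is recorded
    (keeping cost lines consistent with the published norms to the cent),
    otherwise the normalized :func:`annualize` value.
    """
    if uc.printed_annual_usd is not None:
        return inflation_adjust(uc.printed_annual_usd, ctx)
    return annualize(uc, ctx)
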