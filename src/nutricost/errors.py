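"""Exception hierarchy for the costing engine.

All package errors derive from :class:`NutricostError` so callers can catch
one base class; input-validation errors also derive from ``ValueError`` to
behave well in generic numeric code.
"""


class NutricostError(Exception):
    """Base class for all errors raised by nutricost."""


class InvalidInputError(NutricostError, ValueError):
    """A numeric argument is outside its valid domain (negative population,
    prevalence outside [0, 1], growth rate at or below -100%/yr, ...)."""


class InvalidIntervalError(InvalidInputError):
    """An age interval is empty or reversed (hi <= lo)."""


class CoverageError(NutricostError, ValueError):
    """A requested age range falls outside the age bands of a region table."""


class ResolutionError(NutricostError, KeyError):
    """A target rule references a cohort or intervention that does not exist."""


class ConfigurationError(NutricostError):
    """A scenario, unit-cost or rule configuration is internally inconsistent
    (missing convention field, cyclic subtraction chain, duplicate id, ...)."""


class SchemaError(ConfigurationError):
    """Structured input (CSV or scenario config) failed schema validation.

    The message lists the offending file/section/field coordinates.
    """


class UndefinedShareError(NutricostError, ZeroDivisionError):
    """Percentage shares were requested for a report whose grand total is zero."""
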