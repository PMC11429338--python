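"""Exception hierarchy shared across the package."""


class AgegapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AgegapError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(AgegapError, ValueError):
    """A table does not match its column manifest."""


class ContractViolationError(AgegapError, ValueError):
    """A caller violated a hard protocol contract (e.g. AD rows in training data)."""


class DegenerateFitError(AgegapError, ValueError):
    """Too few points, or no spread in x, to fit a line of best fit."""


class EmptyGroupError(AgegapError, ValueError):
    """A diagnostic group required by an operation has no subjects."""


class InsufficientStratumError(AgegapError, ValueError):
    """A stratification level has too few subjects to compose training groups."""


class UndefinedRatioError(AgegapError, ZeroDivisionError):
    """A percent comparison against a zero baseline."""
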