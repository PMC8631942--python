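"""Shared exception types."""


class ShpkitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ShpkitError, ValueError):
    """A parameter violates a documented precondition."""


class DensityError(ShpkitError, RuntimeError):
    """Requested spot density cannot be placed without overlap."""


class UndefinedRatioError(ShpkitError, ValueError):
    """A ratio involving a censored (NOT_DETECTED) or zero operand."""


class IncompleteTableError(ShpkitError, KeyError):
    """An affinity table is missing a required (sh2, motif) record."""


class EmptyRankingError(ShpkitError, ValueError):
    """No feasible binding mode to rank."""


class UndefinedRateError(ShpkitError, ValueError):
    """A rate cannot be computed from an empty denominator set."""


class DegenerateDataError(ShpkitError, ValueError):
    """Input data carry no usable variation for the requested fit."""


class InsufficientDwellsError(ShpkitError, ValueError):
    """Too few uncensored dwells to estimate a rate."""
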