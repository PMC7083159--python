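"""Exception hierarchy.

Everything raised on bad user input derives from :class:`InputError`
(a ``ValueError``), so callers can catch one type at API boundaries.
Contract breaches between components get their own classes.
"""


class CrmlocError(Exception):
    """Base class for all package-specific errors."""


class InputError(CrmlocError, ValueError):
    """Invalid argument values (shapes, ranges, malformed records)."""


class ContractViolationError(CrmlocError, RuntimeError):
    """A model adapter and a feature stack disagree dimensionally."""


class UnsupportedArchitectureError(CrmlocError, RuntimeError):
    """An operation needs a linear GAP head descriptor the model lacks."""


class StateError(CrmlocError, RuntimeError):
    """Operation called before required state was fitted/initialized."""


class NoLungFoundError(InputError):
    """A lung mask contains no foreground pixels."""


class PlacementError(CrmlocError, RuntimeError):
    """Lesions could not be placed inside the lung fields."""


class ParseError(InputError):
    """A CSV/annotation file violates its dialect."""
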