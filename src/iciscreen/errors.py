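"""Exception hierarchy."""


class IciScreenError(Exception):
    """Base class for all package errors."""


class FormatError(IciScreenError):
    """An input file does not follow the documented dialect."""


class ValidationError(IciScreenError):
    """Data violate a contract (negative expression, missing event flag, ...)."""


class MergeError(IciScreenError):
    """Datasets cannot be combined (e.g. sample identifier collision)."""


class StateError(IciScreenError):
    """An operation was applied at the wrong normalization state."""


class DegenerateCohortError(IciScreenError):
    """A cohort ended up with zero responders or zero non-responders."""
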