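"""Exception hierarchy for the rughc package."""


class RughcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RughcError):
    """A configuration object or file is invalid (names the offending field)."""


class ClassificationError(RughcError):
    """An assessment record cannot be classified (missing or invalid item)."""


class DataError(RughcError):
    """Input data violate a documented contract (unknown discipline, negative hours, ...)."""


class ModelError(RughcError):
    """A regression model cannot be fitted (rank deficiency, degenerate outcome)."""
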