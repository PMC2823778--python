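"""Exception hierarchy shared across the toolkit."""


class LMP2MSError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LMP2MSError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class InsufficientDataError(LMP2MSError, ValueError):
    """Too few usable observations for the requested fit or test."""


class DegenerateDecayError(LMP2MSError, ValueError):
    """Substrate signal vanished everywhere after time zero; no decay fit possible."""


class UndefinedSPError(LMP2MSError, ValueError):
    """Specific production is undefined (no substrate was consumed)."""


class MonomorphicLocusError(LMP2MSError, ValueError):
    """Linkage disequilibrium is undefined for a monomorphic locus."""


class SchemaError(LMP2MSError, ValueError):
    """An input table violates the expected column schema."""
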