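"""Exception hierarchy shared across the package."""


class MutaspecError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(MutaspecError, ValueError):
    """A model parameter or argument is outside its mathematical domain."""


class InsufficientDataError(MutaspecError, ValueError):
    """Too few (or degenerate) observations for the requested fit."""


class NoCrossingError(MutaspecError, ValueError):
    """A tabulated curve never crosses the requested threshold."""


class ConfigurationError(MutaspecError, ValueError):
    """An invalid pipeline or simulation configuration."""


class VcfFormatError(MutaspecError, ValueError):
    """A variant file could not be parsed at the container level."""


class FieldValidationError(MutaspecError, ValueError):
    """A parsed record violates a field-level invariant."""


class DataError(MutaspecError, ValueError):
    """Input records are internally inconsistent (e.g. duplicate loci)."""


class InapplicableTestError(MutaspecError, ValueError):
    """A statistical test cannot be applied to the given data."""
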