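"""Exception hierarchy shared across the package."""


class CubkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CubkitError):
    """A coding sequence violates a structural invariant."""


class EmptyInputError(CubkitError):
    """An operation received an empty collection where >= 1 item is required."""


class PrematureStopError(ValidationError):
    """An internal (non-terminal) stop codon was encountered during translation."""


class UndefinedMetricError(CubkitError):
    """A metric is mathematically undefined for the given input."""


class EncUndefinedError(UndefinedMetricError):
    """Wright's effective number of codons cannot be estimated for this gene."""
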