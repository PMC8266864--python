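"""Exception hierarchy shared across the pipeline stages."""


class NatrajError(Exception):
    """Base class for all package errors."""


class FormatError(NatrajError, ValueError):
    """A file does not conform to the expected tab-delimited layout."""


class ValidationError(NatrajError, ValueError):
    """Data violate an invariant (duplicate IDs, unknown vocabulary token...)."""


class ConfigurationError(NatrajError, ValueError):
    """A configuration object violates its own invariants."""


class DesignError(NatrajError, ValueError):
    """A model design cannot be satisfied by the given samples."""


class NormalizationError(NatrajError, ValueError):
    """Size-factor estimation is impossible (e.g. empty reference gene set)."""


class DataError(NatrajError, ValueError):
    """Numeric data are unusable (non-finite values, wrong shape...)."""
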