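"""Exception types raised across the pipeline."""


class LocumCompareError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LocumCompareError):
    """Invalid generator or pipeline configuration (non-finite effects, bad shares...)."""


class IntegrityError(LocumCompareError):
    """A bundle violates its schema or referential/temporal invariants."""


class DefinitionError(LocumCompareError):
    """A prescribing-safety indicator definition is malformed or references
    an unknown codelist group."""


class CapacityError(LocumCompareError):
    """Not enough suitable patients to host the requested scenario cases."""


class EstimationError(LocumCompareError):
    """A model cannot be estimated (single-class outcome, empty data...)."""
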