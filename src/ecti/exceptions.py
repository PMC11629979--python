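"""Exception hierarchy shared across the package."""


class EctiError(Exception):
    """Base class for all package errors."""


class FormatError(EctiError, ValueError):
    """A file does not conform to the expected on-disk format."""


class DataError(EctiError, ValueError):
    """File parsed but its values violate a data contract (e.g. NaN heights)."""


class ParameterError(EctiError, ValueError):
    """An argument is outside its documented domain."""


class EmptyInputError(EctiError, ValueError):
    """An operation that needs at least one element received none."""


class UndefinedMetricError(EctiError, ValueError):
    """A metric is mathematically undefined for the given inputs (e.g. AP with no ground truth)."""


class CapacityError(EctiError, RuntimeError):
    """Requested object density cannot be realised within the available area."""
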