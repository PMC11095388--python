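"""Exception hierarchy shared across the package."""


class ExcitonKitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ExcitonKitError):
    """Invalid user-supplied configuration (unknown element, overlapping QC sets, ...)."""


class FormatError(ExcitonKitError):
    """Malformed or inconsistent input file."""


class DomainError(ExcitonKitError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class NumericalSafetyError(ExcitonKitError):
    """A computation was aborted because it would be numerically unsafe."""


class ContractViolation(ExcitonKitError):
    """An internal pre/post-condition was violated (e.g. non-symmetric matrix)."""


class PipelineError(ExcitonKitError):
    """Inconsistent data handed between pipeline stages."""


class GenerationError(ExcitonKitError):
    """The synthetic-data generator could not satisfy its constraints."""
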