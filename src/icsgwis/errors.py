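"""Exception hierarchy shared across the pipeline stages."""


class IcsGwisError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(IcsGwisError, ValueError):
    """A numeric parameter is outside its documented range."""


class DimensionError(IcsGwisError, ValueError):
    """Input arrays disagree in length or shape."""


class InvalidDataError(IcsGwisError, ValueError):
    """Input data violate a precondition (non-finite values, bad file content)."""


class DegenerateOutcomeError(IcsGwisError, ValueError):
    """The binary outcome has a single class among complete cases."""


class UndefinedFrequencyError(IcsGwisError, ValueError):
    """Allele frequency requested for a variant with no called genotypes."""


class ConfigError(IcsGwisError, ValueError):
    """Pipeline configuration is missing or inconsistent."""


class EstimationError(IcsGwisError, RuntimeError):
    """A Monte-Carlo estimate could not be formed (e.g. every fit failed)."""
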