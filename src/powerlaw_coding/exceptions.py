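"""Exception hierarchy for the power-law coding package."""


class PowerLawCodingError(ValueError):
    """Base class for all package-specific errors."""


class UnsupportedDimensionError(PowerLawCodingError):
    """Raised when an operation requires input dimension D = 1.

    Sampling and decoding are defined only for a one-dimensional circular
    stimulus; the closed-form theory covers general D, but the generative
    basis construction for D > 1 is not implemented.
    """


class DegenerateModelError(PowerLawCodingError):
    """Raised when the noise configuration makes the model degenerate.

    With both noise sources at zero the response is deterministic, the
    Fisher information is infinite and the likelihood is a point mass.
    """


class EstimationFailedError(PowerLawCodingError):
    """Raised when the likelihood surface carries no information about the
    stimulus (e.g. it is flat over the whole circle)."""


class ConfigError(PowerLawCodingError):
    """Raised for invalid or unknown experiment configuration entries."""
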