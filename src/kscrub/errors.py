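"""Exception hierarchy used across the package."""


class KscrubError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KscrubError, ValueError):
    """Invalid parameter value, shape mismatch, or inconsistent options."""


class FormatError(KscrubError, IOError):
    """On-disk artifact missing, malformed, or of the wrong dimensionality."""


class DegenerateInputError(KscrubError, ValueError):
    """Input is structurally valid but carries no usable signal."""


class TrainingDivergedError(KscrubError, RuntimeError):
    """The training loss became non-finite."""


class SolverError(KscrubError, RuntimeError):
    """An iterative solver produced a non-finite iterate."""
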