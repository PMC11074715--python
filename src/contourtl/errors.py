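"""Exception types shared across the pipeline stages."""


class ContourTLError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ContourTLError, ValueError):
    """A parameter or input violates a documented precondition."""


class NoContourFound(ContourTLError):
    """Preprocessing produced a blank mask: no foreground component to crop."""


class DegenerateHistogram(ContourTLError):
    """Threshold selection requires at least two distinct grey levels."""


class LeakageError(ContourTLError):
    """Train and test manifests share a path or a source image."""


class NoSolution(ContourTLError):
    """No integer confusion matrix reproduces the printed metric values."""


class AmbiguousSolution(ContourTLError):
    """More than one confusion matrix reproduces the printed metric values."""
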