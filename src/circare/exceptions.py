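"""Exception hierarchy for the circare pipeline.

All pipeline errors derive from :class:`CircareError` so callers (and the CLI)
can distinguish input problems from genuine bugs.
"""


class CircareError(Exception):
    """Base class for all circare errors."""


class InvalidInputError(CircareError):
    """Malformed input data: negative counts, non-uniform timestamps, bad parameters."""


class InvalidParameterError(CircareError):
    """A configuration or algorithm parameter is out of its admissible range."""


class InsufficientDataError(CircareError):
    """Fewer valid days (or paired subjects) than the method requires.

    Carries ``n_valid`` with the number actually available.
    """

    def __init__(self, message: str, n_valid: int | None = None):
        super().__init__(message)
        self.n_valid = n_valid


class ImputationError(CircareError):
    """A missing epoch could not be filled from any observed neighbour."""


class DegenerateInputError(CircareError):
    """Input with no usable signal (e.g. an all-zero record has zero energy)."""


class FitFailureError(CircareError):
    """Nonlinear fit failed to converge from every start; carries the RSS trace."""

    def __init__(self, message: str, rss_trace: list | None = None):
        super().__init__(message)
        self.rss_trace = rss_trace or []
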