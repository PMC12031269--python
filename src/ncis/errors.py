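"""Exception hierarchy for the ncis package."""


class NcisError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NcisError, ValueError):
    """A physical argument is out of its valid domain (e.g. kappa <= 0)."""


class InvalidGeometryError(NcisError, ValueError):
    """A geometric constraint is violated (e.g. r1 > r2)."""


class InsufficientDataError(NcisError, ValueError):
    """Not enough distinct data points for the requested operation."""


class DegenerateDataError(NcisError, ValueError):
    """The data carry no usable signal (e.g. a constant curve)."""


class FitFailureError(NcisError, RuntimeError):
    """A nonlinear fit failed to converge."""


class ParseError(NcisError, ValueError):
    """A text file could not be parsed; carries file path and line number."""

    def __init__(self, path, line, message):
        self.path = str(path)
        self.line = line
        super().__init__(f"{self.path}:{line}: {message}")
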