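"""Exception types used across the package."""


class FullerbindError(Exception):
    """Base class for package-specific errors."""


class ParseError(FullerbindError):
    """A structure, topology or trajectory file failed to parse.

    Carries the offending line or frame number when known.
    """

    def __init__(self, message, line=None, frame=None):
        self.line = line
        self.frame = frame
        where = ""
        if line is not None:
            where = f" (line {line})"
        elif frame is not None:
            where = f" (frame {frame})"
        super().__init__(message + where)


class TopologyError(FullerbindError):
    """Topology table inconsistent with the coordinate set."""


class ConvergenceError(FullerbindError):
    """Iterative solver failed to reach the requested tolerance."""

    def __init__(self, message, residual=None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (residual {residual:.3e})"
        super().__init__(message)
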