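"""Exception hierarchy shared across the pipeline."""


class TouchnetError(Exception):
    """Base class for all package errors."""


class SwcFormatError(TouchnetError):
    """Malformed SWC input. Carries the offending line number when known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(TouchnetError):
    """Invalid argument or inconsistent in-memory structure."""


class PlacementError(TouchnetError):
    """Soma placement could not satisfy its constraints."""


class RepairError(TouchnetError):
    """Morphology repair could not be carried out."""


class DependencyError(TouchnetError):
    """A pipeline stage was invoked before its prerequisites exist."""
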