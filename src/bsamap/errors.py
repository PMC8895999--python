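"""Exception types shared across the package."""


class BsamapError(Exception):
    """Base class for package errors."""


class ConfigError(BsamapError):
    """Invalid configuration or parameter value."""


class FormatError(BsamapError):
    """A file violated its format's structural contract."""


class ParseError(FormatError):
    """A line could not be parsed; message names the offending line."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class SimulationError(BsamapError):
    """The forward simulation reached an invalid state."""
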