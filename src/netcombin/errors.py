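"""Exception types shared across the package."""


class NetcombinError(Exception):
    """Base class for all package-specific errors."""


class TripletParseError(NetcombinError):
    """A triplet file line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(NetcombinError):
    """An input violates a documented precondition."""
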