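"""Exception hierarchy shared across the package."""


class CoexmodError(Exception):
    """Base class for all coexmod errors."""


class InputFileError(CoexmodError):
    """A required input file is missing or unreadable."""


class MatrixFormatError(CoexmodError):
    """An input file exists but violates the expected format."""


class ParameterError(CoexmodError, ValueError):
    """A parameter value is outside its documented domain."""
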