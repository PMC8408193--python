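"""Exception hierarchy shared across the package."""


class PosesegError(Exception):
    """Base class for all errors raised by poseseg."""


class FormatError(PosesegError):
    """A file does not follow the expected dialect (header, columns...)."""


class SchemaError(PosesegError):
    """Feature/body-part schema of an input does not match the model."""


class ParameterError(PosesegError):
    """A parameter value is outside its supported range."""


class InsufficientDataError(PosesegError):
    """Not enough samples to perform the requested computation."""
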