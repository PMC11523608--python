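"""Exception hierarchy for the fossa-gii toolkit."""


class FossaGiiError(Exception):
    """Base class for all package errors."""


class FormatError(FossaGiiError):
    """A file could not be parsed in its declared format."""


class ValidationError(FossaGiiError):
    """An input violates a documented precondition."""


class ResolutionError(FossaGiiError):
    """A required input file or sampling resolution cannot be satisfied."""


class DegenerateInputError(ValidationError):
    """A statistical routine received input with no usable variation."""


class ConfigError(FossaGiiError):
    """A run configuration contains unknown or inconsistent keys."""
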