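"""Exception hierarchy shared across the pipeline."""


class ChiselError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ChiselError, ValueError):
    """A configuration value violates its constraint."""


class ValidationError(ChiselError, ValueError):
    """Input data violates a documented precondition."""


class FormatError(ChiselError, ValueError):
    """A file could not be decoded as the expected format."""


class CapacityError(ChiselError, ValueError):
    """A requested synthetic scene cannot be packed."""


class StateError(ChiselError, RuntimeError):
    """An object was used before it was trained/initialized."""
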