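"""Exception hierarchy shared across the package."""


class RnaboundError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(RnaboundError, ValueError):
    """A parameter value violates its documented range or relationship."""


class ContractError(RnaboundError, ValueError):
    """An operation was called outside its documented preconditions."""


class MatrixParseError(RnaboundError, ValueError):
    """A base-pair matrix stream could not be parsed; message names the line."""


class GeometryError(ParameterError):
    """A planted structure layout does not fit the requested interval."""
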