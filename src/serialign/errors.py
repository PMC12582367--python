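"""Exception types shared across the pipeline."""


class SerialignError(Exception):
    """Base class for all package errors."""


class FormatError(SerialignError):
    """A file is missing, unreadable, or not in the expected format."""


class ArgumentError(SerialignError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(SerialignError, ValueError):
    """Input carries no usable signal (constant image, zero variance, ...)."""


class IntegrityError(SerialignError):
    """Data violates a table invariant (duplicate ids, invalid polygon, ...)."""


class RegistrationError(SerialignError):
    """The optimizer could not produce a usable transform."""
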