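"""Exception hierarchy shared across the package."""


class RotposError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RotposError, ValueError):
    """A parameter violates an operation's precondition."""


class InvalidStateError(RotposError, RuntimeError):
    """An input object is in the wrong state for the operation (e.g. an
    unnormalized energy track fed to the Boltzmann score)."""


class EmptyTrackError(RotposError, ValueError):
    """The operation cannot produce a single defined value."""


class ParseError(RotposError, ValueError):
    """A file could not be parsed; message carries file/line context."""
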