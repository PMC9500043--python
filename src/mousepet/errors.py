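"""Exception hierarchy shared across the toolbox."""


class MousePETError(Exception):
    """Base class for all toolbox errors."""


class FormatError(MousePETError):
    """Unreadable or unsupported image file."""


class GeometryError(MousePETError):
    """Image geometry outside what the toolbox supports (e.g. oblique affine)."""


class ValidationError(MousePETError, ValueError):
    """Inputs violate an operation's preconditions."""


class RegistrationFailure(MousePETError):
    """A registration stage could not produce a usable transform."""
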