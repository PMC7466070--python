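"""Exception types shared across the package."""


class DermaquantError(Exception):
    """Base class for all package errors."""


class ValidationError(DermaquantError, ValueError):
    """A parameter or input violated a documented precondition.

    The message always names the offending field or argument.
    """


class EmptySectionError(DermaquantError):
    """No tissue was found above the background threshold."""


class NoJunctionError(DermaquantError):
    """Epidermis and dermis masks are nowhere adjacent."""
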