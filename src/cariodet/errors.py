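"""Exception hierarchy.

All package errors derive from :class:`CariodetError` so callers can catch
one base class; each subclass also derives from the matching builtin so that
generic handling (``except ValueError``) keeps working.
"""


class CariodetError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CariodetError, ValueError):
    """Inconsistent physical geometry (e.g. irregular DICOM slice spacing)."""


class ConfigurationError(CariodetError, ValueError):
    """Invalid configuration value or incompatible network/input geometry."""


class DomainError(CariodetError, ValueError):
    """Input outside the operation's domain (e.g. empty mask, one-class labels)."""


class ValidationError(CariodetError, ValueError):
    """Structured validation failure; carries a list of messages."""

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
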