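"""Exception hierarchy shared across the package."""


class SeabiomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeabiomeError, ValueError):
    """A file or text input violates its format contract."""


class DomainError(SeabiomeError, ValueError):
    """An argument violates a documented precondition."""
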