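"""Exception hierarchy shared across the toolkit."""


class SatkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SatkitError):
    """A file does not follow the expected on-disk format."""


class IntegrityError(SatkitError):
    """Parsed data violates an invariant (duplicate barcodes, shape mismatch, ...)."""


class ConfigError(SatkitError):
    """Invalid or incomplete run configuration."""


class EmptyResultError(SatkitError):
    """An operation removed or excluded every cell."""
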