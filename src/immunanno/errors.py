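"""Exception types shared across the package."""


class ImmunannoError(Exception):
    """Base class for all package errors."""


class InputError(ImmunannoError, ValueError):
    """Invalid user-supplied data (duplicate barcodes, negative counts, ...)."""


class FormatError(ImmunannoError, ValueError):
    """A file does not conform to its declared format."""


class ConfigError(ImmunannoError, ValueError):
    """Inconsistent hierarchy / run configuration."""


class ScoringError(ImmunannoError, ValueError):
    """A gene set cannot be scored on the given matrix."""
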