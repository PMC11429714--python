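"""Exception hierarchy shared across the package."""


class KinlinkError(Exception):
    """Base class for all package errors."""


class ValidationError(KinlinkError, ValueError):
    """A value or table violates a documented contract."""


class SchemaError(KinlinkError, ValueError):
    """A tabular input is missing required columns or has the wrong types."""


class FormatError(KinlinkError, ValueError):
    """A file does not conform to its declared on-disk format."""


class ParameterError(KinlinkError, ValueError):
    """A generator or scoring parameter is outside its admissible range."""
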