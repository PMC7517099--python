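"""Exception types shared across the package."""


class MemmHarError(Exception):
    """Base class for package errors."""


class SchemaError(MemmHarError, ValueError):
    """A file or object does not match the expected column/field layout."""


class ParseError(MemmHarError, ValueError):
    """A cell or token could not be parsed as the expected type."""


class EmptyInputError(MemmHarError, ValueError):
    """An operation received an input with no data."""
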