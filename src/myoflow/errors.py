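"""Exception types shared across the pipeline."""


class MyoflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MyoflowError):
    """A scene/spec/run configuration violates its invariants."""


class CalibrationError(MyoflowError):
    """Pixel size, frame interval or axis convention is missing or invalid."""


class SchemaError(MyoflowError):
    """A table or file does not match the documented column schema."""


class DimensionError(MyoflowError):
    """Arrays that must share a shape (movie vs. label mask) do not."""
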