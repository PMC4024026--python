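"""Exception hierarchy shared across the pipeline."""


class DceQuantError(Exception):
    """Base class for all package errors."""


class ParameterError(DceQuantError, ValueError):
    """A physical or model parameter is out of its admissible range."""


class ConfigurationError(DceQuantError, ValueError):
    """An acquisition/run configuration is internally inconsistent."""


class DimensionError(DceQuantError, ValueError):
    """Requested geometry does not fit the image volume."""


class InputError(DceQuantError, ValueError):
    """Invalid data passed to an analysis operation."""


class FormatError(DceQuantError, ValueError):
    """A file on disk does not match the expected layout."""
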