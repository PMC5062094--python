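"""Exception types shared across the pipeline."""


class HerpipeError(Exception):
    """Base class for all package errors."""


class ValidationError(HerpipeError, ValueError):
    """A configuration or input value violates its contract."""


class AnalysisError(HerpipeError, RuntimeError):
    """An analysis step cannot proceed (e.g. no usable epochs)."""


class FileFormatError(HerpipeError, IOError):
    """A file on disk does not conform to the expected format."""
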