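"""Exception hierarchy shared across the pipeline."""


class MirgrankError(Exception):
    """Base class for all package errors."""


class InputFormatError(MirgrankError):
    """A file could not be parsed into the expected table layout."""


class DataError(MirgrankError):
    """Parsed data violate a structural requirement (labels, sample ids...)."""


class ParameterError(MirgrankError):
    """A configuration value is outside its valid range."""


class PipelineError(MirgrankError):
    """A pipeline stage cannot proceed (e.g. no miRNA-mRNA associations)."""
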