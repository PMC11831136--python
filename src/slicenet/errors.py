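"""Exception hierarchy shared across the pipeline."""


class SliceNetError(Exception):
    """Base class for all slicenet errors."""


class FormatError(SliceNetError):
    """Input file does not contain the expected structure."""


class ParseError(SliceNetError):
    """A sample name or field could not be parsed."""


class ValidationError(SliceNetError):
    """A contract on the data was violated."""


class PipelineError(SliceNetError):
    """A stage cannot proceed on the given data."""
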