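"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PipelineError` so the CLI can
report the failing stage and exit nonzero without a traceback.
"""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError):
    """A config value, column mapping, or sample design is invalid."""


class TableParseError(PipelineError):
    """A tabular input file could not be parsed (row/column context in message)."""


class FastaFormatError(PipelineError):
    """A FASTA record is malformed (empty sequence, duplicate accession, ...)."""


class StateError(PipelineError):
    """An operation was called on data in the wrong state (e.g. ratios before imputation)."""
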