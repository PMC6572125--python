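"""Exception hierarchy shared across the pipeline."""


class PhosphopipeError(Exception):
    """Base class for all package errors."""


class FormatError(PhosphopipeError):
    """A file does not conform to the documented dialect (missing columns,
    malformed FASTA/GMT lines, empty file)."""


class ValidationError(PhosphopipeError):
    """Structurally parseable input that violates a domain invariant
    (duplicate channels, no control sample, probability outside [0,1], ...)."""


class DegenerateInputError(PhosphopipeError):
    """Input that makes a statistic undefined (e.g. zero spread of all
    fold-changes in kinase enrichment)."""
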