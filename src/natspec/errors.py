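"""Exception hierarchy shared across the pipeline."""


class NatspecError(Exception):
    """Base class for all pipeline errors."""


class FormatError(NatspecError):
    """Malformed input file (FASTA/GFF3/config)."""


class CoordinateError(NatspecError):
    """Feature coordinates fall outside their contig."""


class EmptyInputError(NatspecError):
    """An operation received an empty sequence, genome or gene set."""


class ArgumentError(NatspecError):
    """Invalid argument value (thresholds, replicate counts, ...)."""


class UndefinedMetricError(NatspecError):
    """A relatedness metric has no value (e.g. no matched segments)."""
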