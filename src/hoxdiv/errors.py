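"""Exception hierarchy shared across the package."""


class HoxdivError(Exception):
    """Base class for all package errors."""


class FormatError(HoxdivError):
    """Malformed input file (FASTA, TSV, config)."""


class ValidationError(HoxdivError):
    """Inputs violate a documented precondition or invariant."""


class UndefinedResultError(HoxdivError):
    """A quantity is mathematically undefined for the given input
    (e.g. a p-distance with zero comparable sites)."""
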