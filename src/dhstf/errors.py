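"""Exception hierarchy shared across the pipeline stages."""


class DhstfError(Exception):
    """Base class for all package errors."""


class ParseError(DhstfError):
    """A record in an input file could not be parsed."""


class EmptyInputError(DhstfError):
    """An operation received an empty collection where data is required."""


class DomainError(DhstfError):
    """A numeric argument lies outside the mathematical domain (e.g. log of zero)."""


class SequenceLengthError(DhstfError):
    """A sequence is shorter than the motif being scanned."""


class AlignmentError(DhstfError):
    """Row/column identifiers of two matrices do not line up."""


class ParameterError(DhstfError):
    """A run parameter is outside its valid range."""


class FeasibilityError(DhstfError):
    """A synthetic layout cannot be realised (e.g. too many genes per chromosome)."""
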