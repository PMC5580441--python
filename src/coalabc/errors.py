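"""Exception hierarchy shared across the package."""


class CoalABCError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(CoalABCError):
    """Structural problem in an alignment (ragged rows, fully trimmed, ...)."""


class FormatError(CoalABCError):
    """Unparseable or malformed input file."""


class MetadataError(CoalABCError):
    """Inconsistent sample metadata (duplicate ids, unknown taxon, ...)."""


class InsufficientDataError(CoalABCError):
    """Too few sequences/rows to compute the requested statistic."""


class UndefinedStatisticError(CoalABCError):
    """The statistic is mathematically undefined for this input.

    Raised instead of returning 0.0 so callers can distinguish "no
    divergence observed" from "no comparable sites at all".
    """


class ScopeError(CoalABCError):
    """Requested combination is outside the analysis design.

    E.g. the isolation-migration models (F, G) were defined for the
    nuclear track only.
    """


class ABCError(CoalABCError):
    """Invalid ABC configuration (bad tolerance, mismatched vectors, ...)."""
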