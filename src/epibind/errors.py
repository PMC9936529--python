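"""Exception hierarchy shared across the package."""


class EpibindError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EpibindError):
    """A structure or score file could not be parsed."""


class EmptyStructureError(ParseError):
    """A coordinate file yielded zero atoms."""


class TopologyError(EpibindError):
    """Frames of a trajectory disagree on atom identity or count."""


class SelectionError(EpibindError):
    """A selection expression is invalid or refers to unknown atoms."""


class ValidationError(EpibindError):
    """A value violates a documented domain invariant."""


class DegenerateFitError(EpibindError):
    """Too few or collinear fit atoms for a rigid-body superposition."""


class PairingError(EpibindError):
    """Antigen atoms could not be paired between two structures."""


class EmptyChainError(EpibindError):
    """An operation would silently delete an entire chain."""


class UndefinedRatioError(EpibindError):
    """A ratio statistic has a zero denominator."""


class SolverError(EpibindError):
    """Numerical integration of a kinetic model failed."""
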