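"""Geometric thresholds and protocol defaults used throughout the pipeline.

The defaults are the conventions of the study this pipeline reproduces:
contacts between heavy atoms closer than 4.5 A, hydrogen bonds with a
donor-acceptor distance of at most 3.5 A and a near-linear D-H...A angle
(>= 150 deg), steric clashes below 3.0 A (0.3 nm), terminal trimming of
predicted models below pLDDT 70, trajectory subsampling at 1 ns, and a
200 ns plateau window for equilibrated averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``da_cutoff`` is the donor-heavy-atom to acceptor-heavy-atom distance
    (inclusive, "at most"); ``angle_min`` is the minimum three-point
    D-H...A angle at the hydrogen in degrees.  A printed band of
    150-210 deg is the symmetric region |theta - 180| <= 30 of an angle
    that geometrically cannot exceed 180 deg, hence a single lower bound.
    """

    da_cutoff: float = 3.5
    angle_min: float = 150.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValidationError("da_cutoff must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValidationError("angle_min must lie in (0, 180]")


@dataclass(frozen=True)
class AnalysisSettings:
    """All tunable thresholds, with study defaults."""

    contact_cutoff: float = 4.5           # A, strict less-than, heavy atoms
    clash_cutoff: float = 3.0             # A (= 0.3 nm), strict less-than
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    plddt_threshold: float = 70.0         # strict less-than marks low confidence
    subsample_interval: float = 1.0       # ns
    plateau_window: float = 200.0         # ns

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.clash_cutoff <= 0:
            raise ValidationError("distance cutoffs must be positive")
        if self.subsample_interval <= 0:
            raise ValidationError("subsample interval must be positive")
        if self.plateau_window <= 0:
            raise ValidationError("plateau window must be positive")


NM_TO_ANGSTROM = 10.0


def nm(value: float) -> float:
    """Convert a length quoted in nm to the package-internal Angstrom."""
    return value * NM_TO_ANGSTROM
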