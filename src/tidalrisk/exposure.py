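"""Exposure components: array passage and fish-turbine co-occurrence.

Array passage (``P_p``) is the probability that a population member transits
the turbine installation area in one time interval.  Absent telemetry, it is
screened as average movement speed over population range, both expressed in
turbine-array units:  ``P_p = v_p / R_p``, optionally inflated by an affinity
multiplier where the array overlaps preferred habitat, and clamped at 1.

Where field observations of fish flux at rotor depth exist, the joint factor
``P_o x P_p`` is measured directly: standardized fish activity (entries per
m^2 of entrance area per sample), converted to hourly rate, restricted to
along-current swimmers, scaled by the rotor swept area and divided by the
population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "PopulationSpec",
    "ActivityRecord",
    "rotor_swept_area",
    "array_passage",
    "co_occurrence_rate",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Population-scale movement parameters for the array-passage screen.

    ``v_p`` and ``r_p`` are expressed in turbine-array units (the footprint of
    the installation) per time interval; ``affinity`` (>= 1 for preferred
    habitat) scales passage upward.
    """

    n_tot: float
    v_p: float
    r_p: float
    affinity: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.n_tot) and self.n_tot > 0):
            raise DomainError(f"n_tot must be > 0, got {self.n_tot}")
        if not (math.isfinite(self.v_p) and self.v_p >= 0):
            raise DomainError(f"v_p must be >= 0, got {self.v_p}")
        if not (math.isfinite(self.r_p) and self.r_p > 0):
            raise DomainError(f"r_p must be > 0, got {self.r_p}")
        if not (math.isfinite(self.affinity) and self.affinity >= 0):
            raise DomainError(f"affinity must be >= 0, got {self.affinity}")


@dataclass(frozen=True)
class ActivityRecord:
    """Standardized field-observed fish activity for one current-speed bin.

    ``activity`` is fish entries per m^2 of camera entrance area per sample of
    ``sample_duration`` minutes; ``frac_along_current`` is the proportion of
    those fish swimming along-current (the ones that can head into a rotor).
    """

    current_bin: str
    activity: float
    frac_along_current: float
    sample_duration: float = 45.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.activity) and self.activity >= 0):
            raise DomainError(f"activity must be >= 0, got {self.activity}")
        if not (math.isfinite(self.frac_along_current) and 0 <= self.frac_along_current <= 1):
            raise DomainError(
                f"frac_along_current must be in [0, 1], got {self.frac_along_current}"
            )
        if not (math.isfinite(self.sample_duration) and self.sample_duration > 0):
            raise DomainError(f"sample_duration must be > 0, got {self.sample_duration}")


def rotor_swept_area(diameter: float) -> float:
    """Area of the rotor swept disc, ``pi (d/2)^2`` in m^2."""
    if not (math.isfinite(diameter) and diameter > 0):
        raise DomainError(f"diameter must be > 0, got {diameter}")
    return math.pi * (diameter / 2.0) ** 2


def array_passage(pop: PopulationSpec) -> float:
    """Screening estimate of ``P_p``: ``min(1, affinity * v_p / r_p)``."""
    return min(1.0, pop.affinity * pop.v_p / pop.r_p)


def co_occurrence_rate(
    rec: ActivityRecord,
    rotor_area: float,
    n_tot: float,
    interval: float = 1.0,
) -> float:
    """Joint exposure ``P_o x P_p`` per interval from standardized activity data.

    Activity per sample is converted to the assessment interval via
    ``60 * interval / sample_duration`` (interval in hours, duration in
    minutes), restricted to along-current swimmers, multiplied by the rotor
    swept area and divided by population size.  Clamped to [0, 1].
    """
    if not (math.isfinite(rotor_area) and rotor_area > 0):
        raise DomainError(f"rotor_area must be > 0, got {rotor_area}")
    if not (math.isfinite(n_tot) and n_tot > 0):
        raise DomainError(f"n_tot must be > 0, got {n_tot}")
    if not (math.isfinite(interval) and interval > 0):
        raise DomainError(f"interval must be > 0, got {interval}")
    hourly = rec.activity * (60.0 * interval / rec.sample_duration)
    rate = hourly * rec.frac_along_current * rotor_area / n_tot
    return min(1.0, rate)
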