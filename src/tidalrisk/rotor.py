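"""Rotor hazard geometry, blade-incident probability and passage injury.

Only part of the swept disc is hazardous.  An inner safety zone around the
nacelle covers the radii where the local blade speed stays below a harmless
threshold (blade speed grows linearly with radius, so the safe-area fraction
is ``(v_safe / v_tip)^2``).  An outer annulus is effectively safe because the
hydrodynamic bow ahead of the rotor deflects incoming water, and fish, toward
the rim.  The remaining fraction of the disc is the hazard zone ``P_z``;
below the turbine's cut-in current the rotor is parked and ``P_z = 0``.

Within the hazard zone, a blade strikes a transiting fish if a blade sweeps
its trajectory during the time its body takes to clear the rotor plane:

    P_b = n * (rpm/60) * extent / v_cf

where ``extent`` generalizes ``cos(angle_of_attack) * L_f`` with a body-depth
term ``h_f * |sin(angle_of_attack)|`` so that a fish passing sideways-on
still presents its body depth to the blades.  Injury during passage is the OR
of hydraulic stress and a completed strike (incident AND failed evasion AND
damaging impact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError
from .risk_core import and_gate, or_gate

__all__ = [
    "TurbineSpec",
    "PassageState",
    "tip_speed",
    "inner_safe_fraction",
    "hazard_zone",
    "effective_extent",
    "blade_incident",
    "turbine_injury",
    "passage_after_avoidance",
]


@dataclass(frozen=True)
class TurbineSpec:
    """Rotor geometry and kinematics.

    ``v_safe_blade`` is the local blade speed below which strikes are harmless
    (inner safety zone); ``f_outer`` the disc-area fraction of the outer
    deflection zone (~0.10 for large rotors, ~0.20 for small ones).
    """

    diameter: float
    n_blades: int
    rpm: float
    cut_in: float = 0.0
    v_safe_blade: float = 5.0
    f_outer: float = 0.10

    def __post_init__(self) -> None:
        if not (math.isfinite(self.diameter) and self.diameter > 0):
            raise DomainError(f"diameter must be > 0, got {self.diameter}")
        if self.n_blades < 1:
            raise DomainError(f"n_blades must be >= 1, got {self.n_blades}")
        if not (math.isfinite(self.rpm) and self.rpm >= 0):
            raise DomainError(f"rpm must be >= 0, got {self.rpm}")
        if not (math.isfinite(self.cut_in) and self.cut_in >= 0):
            raise DomainError(f"cut_in must be >= 0, got {self.cut_in}")
        if not (math.isfinite(self.v_safe_blade) and self.v_safe_blade >= 0):
            raise DomainError(f"v_safe_blade must be >= 0, got {self.v_safe_blade}")
        if not 0.0 <= self.f_outer < 1.0:
            raise DomainError(f"f_outer must be in [0, 1), got {self.f_outer}")


@dataclass(frozen=True)
class PassageState:
    """Posture and speed of a fish transiting the rotor plane.

    ``angle_of_attack`` is the angle between the fish body axis and the
    turbine's axial (flow) direction: 0 deg for a fish aligned with the flow,
    90 deg for one swimming parallel to the rotor plane.  ``v_cf`` is the
    combined current-plus-fish speed through the plane.
    """

    angle_of_attack: float
    v_cf: float
    effective_extent: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v_cf) and self.v_cf > 0):
            raise DomainError(f"v_cf must be > 0, got {self.v_cf}")


def tip_speed(t: TurbineSpec) -> float:
    """Blade-tip speed ``pi * diameter * rpm / 60`` in m/s."""
    return math.pi * t.diameter * t.rpm / 60.0


def inner_safe_fraction(t: TurbineSpec) -> float:
    """Disc-area fraction where the local blade speed stays <= ``v_safe_blade``.

    The safe radius is ``R * v_safe / v_tip``, so the area fraction is the
    square of the speed ratio, capped at 1.  A parked rotor is entirely safe.
    """
    v_tip = tip_speed(t)
    if v_tip <= t.v_safe_blade:
        return 1.0
    return (t.v_safe_blade / v_tip) ** 2


def hazard_zone(t: TurbineSpec, v_c: float) -> float:
    """Hazardous disc-area fraction ``P_z`` at current speed ``v_c``.

    Zero below cut-in (rotor parked); otherwise the disc minus the inner and
    outer safety zones, floored at zero.
    """
    if not math.isfinite(v_c) or v_c < 0:
        raise DomainError(f"v_c must be >= 0, got {v_c}")
    if v_c < t.cut_in:
        return 0.0
    return max(0.0, 1.0 - inner_safe_fraction(t) - t.f_outer)


def effective_extent(l_f: float, h_f: float, angle_of_attack: float) -> float:
    """Body extent presented along the flow axis at the given angle of attack (m).

    ``l_f |cos a| + h_f |sin a|``: the classic length-projection term plus a
    body-depth term that keeps a sideways-on fish (a = 90 deg) from having
    zero exposure.  With ``h_f = 0`` this is exactly the length-projection
    model.
    """
    if l_f < 0 or h_f < 0:
        raise DomainError(f"l_f and h_f must be >= 0, got {l_f}, {h_f}")
    a = math.radians(angle_of_attack)
    return l_f * abs(math.cos(a)) + h_f * abs(math.sin(a))


def blade_incident(t: TurbineSpec, p: PassageState, l_f: float | None = None,
                   h_f: float = 0.0) -> float:
    """Blade-incident probability ``P_b`` for one rotor passage.

    Uses ``p.effective_extent`` when set, otherwise computes it from ``l_f``,
    ``h_f`` and the angle of attack.  Clamped at 1.
    """
    extent = p.effective_extent
    if extent <= 0.0 and l_f is not None:
        extent = effective_extent(l_f, h_f, p.angle_of_attack)
    if extent < 0:
        raise DomainError(f"effective extent must be >= 0, got {extent}")
    return min(1.0, t.n_blades * (t.rpm / 60.0) * extent / p.v_cf)


def turbine_injury(p_s: float, p_b: float, p_e: float, p_d: float) -> float:
    """Injury probability ``P_i`` during rotor passage.

    OR of hydraulic stress and a completed blade strike:
    ``p_s + p_b*p_e*p_d - p_s*p_b*p_e*p_d``.
    """
    return or_gate([p_s, and_gate([p_b, p_e, p_d])])


def passage_after_avoidance(
    strategy: str,
    v_c: float,
    v_sust: float,
    l_f: float,
    h_f: float = 0.0,
    v_floor: float = 0.05,
) -> PassageState:
    """Posture and speed through the rotor implied by the failed escape strategy.

    A failed 'reverse' fish enters tail-first while still swimming against the
    flow: head-on posture (angle 0) and ground speed ``max(v_floor,
    v_c - v_sust)``, which lengthens its transit and raises ``P_b``.  A failed
    'diverge' fish is carried through sideways-on at the current speed
    (angle 90), a quick transit with only its body depth exposed.
    """
    if strategy == "reverse":
        v_cf = max(v_floor, v_c - v_sust)
        angle = 0.0
    elif strategy == "diverge":
        v_cf = v_c
        angle = 90.0
    else:
        raise DomainError(f"strategy must be 'reverse' or 'diverge', got {strategy!r}")
    return PassageState(
        angle_of_attack=angle,
        v_cf=v_cf,
        effective_extent=effective_extent(l_f, h_f, angle),
    )
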