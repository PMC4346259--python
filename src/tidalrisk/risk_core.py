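"""Fault-tree gate algebra, turbine-mortality combination and population bookkeeping.

The collision-risk model is a fault tree whose top event, *turbine mortality*
(``P_TM``), combines eight basic-event probabilities:

====  =======================================================================
P_p   array passage: a population member transits the installation area
P_o   co-occurrence: a transiting fish heads into an operating rotor disc
P_a   avoidance failure: the fish fails to swim clear after remote detection
P_z   hazard zone: the fish is swept into the hazardous part of the disc
P_s   hydraulic stress causes severe injury during passage
P_b   blade incident: a blade sweeps the fish's trajectory
P_e   evasion failure: the last-moment startle manoeuvre fails
P_d   blade damage: the collision is severe
====  =======================================================================

Injury during rotor passage is an OR of hydraulic stress and a completed
blade strike (blade incident AND evasion failure AND blade damage), so

    P_TM = P_p * P_o * P_a * P_z * (P_s + P_b*P_e*P_d - P_s*P_b*P_e*P_d)

with an optional approximation that drops the cross term.  Multiplying
``P_TM`` by the population size gives the expected number of turbine-caused
deaths per time interval; summing interval totals weighted by hours per year
gives a yearly loss, which enters a simple births/deaths/migration budget for
the population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Tuple

from .errors import DomainError

__all__ = [
    "LIGHT_LEVELS",
    "RiskComponents",
    "Setting",
    "PopulationState",
    "and_gate",
    "or_gate",
    "turbine_mortality",
    "expected_mortalities",
    "yearly_total",
    "project_population",
]

#: Valid light-condition labels used throughout the package.
LIGHT_LEVELS = ("daylight", "lowlight")


def _check_probability(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise DomainError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must be a finite probability in [0, 1], got {value}")
    return value


def and_gate(probs: Iterable[float]) -> float:
    """Probability that all independent events occur: the product of ``probs``."""
    out = 1.0
    for i, p in enumerate(probs):
        out *= _check_probability(f"probs[{i}]", p)
    return out


def or_gate(probs: Iterable[float]) -> float:
    """Probability that at least one independent event occurs.

    Computed by inclusion-exclusion as ``1 - prod(1 - p_i)``.
    """
    miss = 1.0
    for i, p in enumerate(probs):
        miss *= 1.0 - _check_probability(f"probs[{i}]", p)
    return 1.0 - miss


@dataclass(frozen=True)
class RiskComponents:
    """The eight basic-event probabilities for one setting.

    ``p_op``, when given, is a joint exposure factor ``P_o x P_p`` measured
    directly from field data (fish passing the rotor per interval divided by
    population size); it takes precedence over the separate ``p_p * p_o``
    product.
    """

    p_p: float = 1.0
    p_o: float = 1.0
    p_a: float = 1.0
    p_z: float = 1.0
    p_s: float = 0.0
    p_b: float = 0.0
    p_e: float = 0.0
    p_d: float = 0.0
    p_op: float | None = None

    def __post_init__(self) -> None:
        for name in ("p_p", "p_o", "p_a", "p_z", "p_s", "p_b", "p_e", "p_d"):
            _check_probability(name, getattr(self, name))
        if self.p_op is not None:
            _check_probability("p_op", self.p_op)

    @property
    def exposure(self) -> float:
        """Joint exposure probability ``P_o x P_p`` for the interval."""
        if self.p_op is not None:
            return self.p_op
        return self.p_p * self.p_o


@dataclass(frozen=True)
class Setting:
    """A tidal-current x light condition with its yearly hour budget."""

    label: str
    current_speed: float
    light: str
    hours: float
    components: RiskComponents

    def __post_init__(self) -> None:
        if self.light not in LIGHT_LEVELS:
            raise DomainError(f"light must be one of {LIGHT_LEVELS}, got {self.light!r}")
        if not (math.isfinite(self.hours) and self.hours >= 0):
            raise DomainError(f"hours must be >= 0, got {self.hours}")
        if not (math.isfinite(self.current_speed) and self.current_speed >= 0):
            raise DomainError(f"current_speed must be >= 0, got {self.current_speed}")


def turbine_mortality(c: RiskComponents, exact: bool = True) -> float:
    """Top-event probability of turbine mortality for one interval.

    Parameters
    ----------
    c
        Basic-event probabilities (joint ``p_op`` takes precedence over
        ``p_p * p_o``).
    exact
        If True (default) use the full OR combination for rotor-passage
        injury, ``P_s + P_b*P_e*P_d - P_s*P_b*P_e*P_d``.  If False, drop the
        cross term; the approximation is never smaller than the exact value.
    """
    strike = c.p_b * c.p_e * c.p_d
    injury = c.p_s + strike
    if exact:
        injury -= c.p_s * strike
    return c.exposure * c.p_a * c.p_z * injury


def expected_mortalities(p_tm: float, n_tot: float) -> float:
    """Expected number of turbine-caused deaths in the interval: ``P_TM x N_TOT``."""
    _check_probability("p_tm", p_tm)
    if not (math.isfinite(n_tot) and n_tot >= 0):
        raise DomainError(f"n_tot must be >= 0, got {n_tot}")
    return p_tm * n_tot


def yearly_total(settings: Iterable[Tuple[float, float]]) -> float:
    """Yearly expected loss: sum of hourly expected mortalities x hours per setting.

    ``settings`` is an iterable of ``(hourly_n_tm, hours)`` pairs.
    """
    total = 0.0
    for i, (hourly, hours) in enumerate(settings):
        if not (math.isfinite(hours) and hours >= 0):
            raise DomainError(f"settings[{i}]: hours must be >= 0, got {hours}")
        if not math.isfinite(hourly) or hourly < 0:
            raise DomainError(f"settings[{i}]: hourly value must be >= 0, got {hourly}")
        total += hourly * hours
    return total


@dataclass(frozen=True)
class PopulationState:
    """Population size together with its yearly demographic rates.

    Rates are individuals per year: births, immigration, deaths (natural and
    other anthropogenic), emigration, and turbine mortality.
    """

    n_tot: float
    rate_births: float = 0.0
    rate_immigration: float = 0.0
    rate_deaths: float = 0.0
    rate_emigration: float = 0.0
    rate_turbine_mortality: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.n_tot) and self.n_tot >= 0):
            raise DomainError(f"n_tot must be >= 0, got {self.n_tot}")


def project_population(state: PopulationState, dt: float) -> PopulationState:
    """Forward-Euler step of the population budget over ``dt`` years.

    dN/dt = births + immigration - deaths - emigration - turbine mortality.
    The projected size is floored at zero (abundance cannot be negative); the
    rates themselves are carried over unchanged.
    """
    if not (math.isfinite(dt) and dt > 0):
        raise DomainError(f"dt must be > 0, got {dt}")
    net = (
        state.rate_births
        + state.rate_immigration
        - state.rate_deaths
        - state.rate_emigration
        - state.rate_turbine_mortality
    )
    return replace(state, n_tot=max(0.0, state.n_tot + dt * net))
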