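"""Scenario configuration, validation and end-to-end risk runs.

A scenario bundles a turbine, a fish description (point traits and/or trait
distributions), a population, assigned passage probabilities and a list of
current x light settings with their yearly hour budgets.  Running it resolves
every basic-event probability per setting — exposure from field activity
data, a joint override, or the movement screen; avoidance failure by Monte
Carlo or override; hazard zone and blade incident from rotor geometry;
evasion/damage/stress from assigned values — combines them through the fault
tree and aggregates hourly expected losses into a yearly total.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field as dc_field
from typing import Any, Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import avoidance, exposure, risk_core, rotor
from .errors import ScenarioValidationError

__all__ = ["Scenario", "ScenarioResult", "load_scenario", "run_scenario", "write_report"]


_LIGHTS = risk_core.LIGHT_LEVELS


@dataclass
class Scenario:
    """A validated scenario configuration (see ``Scenario.from_dict``)."""

    turbine: rotor.TurbineSpec
    settings: List[Dict[str, Any]]
    population: Optional[exposure.PopulationSpec] = None
    traits: Optional[Dict[str, float]] = None
    distributions: Optional[Dict[str, avoidance.TraitDistribution]] = None
    strategy: str = "reverse"
    assigned: Dict[str, Any] = dc_field(default_factory=dict)
    activity: Dict[str, exposure.ActivityRecord] = dc_field(default_factory=dict)
    runs: int = 100_000
    seed: Optional[int] = None
    exact: bool = True
    raw: Dict[str, Any] = dc_field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "Scenario":
        """Build and validate a scenario from a plain configuration mapping.

        Every violation found is collected and reported together in a single
        ``ScenarioValidationError`` naming the offending fields.
        """
        problems: List[str] = []
        cfg = copy.deepcopy(dict(cfg))

        turbine = None
        tb = cfg.get("turbine")
        if not isinstance(tb, Mapping):
            problems.append("turbine: block is required")
        else:
            try:
                turbine = rotor.TurbineSpec(
                    diameter=tb.get("diameter", 0.0),
                    n_blades=tb.get("n_blades", 1),
                    rpm=tb.get("rpm", 0.0),
                    cut_in=tb.get("cut_in", 0.0),
                    v_safe_blade=tb.get("v_safe_blade", 5.0),
                    f_outer=tb.get("f_outer", 0.10),
                )
                if rotor.inner_safe_fraction(turbine) + turbine.f_outer > 1.0:
                    problems.append(
                        "turbine: inner_safe_fraction + f_outer exceeds 1 "
                        "(safety zones cannot overlap the whole disc)"
                    )
            except Exception as exc:
                problems.append(f"turbine: {exc}")

        population = None
        pb = cfg.get("population")
        if isinstance(pb, Mapping):
            try:
                population = exposure.PopulationSpec(
                    n_tot=pb.get("n_tot", 0.0),
                    v_p=pb.get("v_p", 0.0),
                    r_p=pb.get("r_p", 0.0),
                    affinity=pb.get("affinity", 1.0),
                )
            except Exception as exc:
                problems.append(f"population: {exc}")
        elif pb is not None:
            problems.append("population: must be a mapping")

        fish = cfg.get("fish", {}) or {}
        strategy = fish.get("strategy", "reverse")
        if strategy not in avoidance.STRATEGIES:
            problems.append(f"fish.strategy: must be one of {avoidance.STRATEGIES}")
        traits = fish.get("traits")
        dists: Optional[Dict[str, avoidance.TraitDistribution]] = None
        if "distributions" in fish:
            dists = {}
            for name, spec in fish["distributions"].items():
                try:
                    bounds = spec.get("bounds")
                    dists[name] = avoidance.TraitDistribution(
                        name=name,
                        family=spec["family"],
                        params=tuple(spec["params"]),
                        bounds=tuple(bounds) if bounds is not None else None,
                    )
                except Exception as exc:
                    problems.append(f"fish.distributions.{name}: {exc}")

        assigned = cfg.get("assigned", {}) or {}
        for key, val in assigned.items():
            vals = val.values() if isinstance(val, Mapping) else [val]
            for v in vals:
                if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                    problems.append(f"assigned.{key}: values must be probabilities in [0,1]")

        activity: Dict[str, exposure.ActivityRecord] = {}
        for i, rec in enumerate(cfg.get("activity", []) or []):
            try:
                r = exposure.ActivityRecord(
                    current_bin=rec["current_bin"],
                    activity=rec["activity"],
                    frac_along_current=rec["frac_along_current"],
                    sample_duration=rec.get("sample_duration_min", 45.0),
                )
                activity[r.current_bin] = r
            except Exception as exc:
                problems.append(f"activity[{i}]: {exc}")

        run = cfg.get("run", {}) or {}
        runs = int(run.get("runs", 100_000))
        if runs < 1:
            problems.append("run.runs: must be >= 1")
        seed = run.get("seed")
        exact = bool(run.get("exact", True))

        settings = cfg.get("settings")
        if not settings:
            problems.append("settings: at least one setting is required")
            settings = []
        total_hours = 0.0
        for i, s in enumerate(settings):
            label = s.get("label", f"settings[{i}]")
            if s.get("light") not in _LIGHTS:
                problems.append(f"{label}: light must be one of {_LIGHTS}")
            v = s.get("current_speed")
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                problems.append(f"{label}: current_speed must be >= 0")
            h = s.get("hours", 0.0)
            if not (isinstance(h, (int, float)) and h >= 0):
                problems.append(f"{label}: hours must be >= 0")
            else:
                total_hours += h
            for key, val in (s.get("overrides") or {}).items():
                if not (isinstance(val, (int, float)) and 0.0 <= val <= 1.0):
                    problems.append(f"{label}.overrides.{key}: must be a probability in [0,1]")
        if total_hours > 8766.0:
            problems.append(f"settings: hours sum to {total_hours:.0f} > 8766 (one year)")

        if problems:
            raise ScenarioValidationError(problems)
        return cls(
            turbine=turbine, settings=list(settings), population=population,
            traits=dict(traits) if traits else None, distributions=dists,
            strategy=strategy, assigned=dict(assigned), activity=activity,
            runs=runs, seed=seed, exact=exact, raw=cfg,
        )

    def to_dict(self) -> Dict[str, Any]:
        """The normalized configuration mapping this scenario was built from."""
        return copy.deepcopy(self.raw)


def load_scenario(path) -> Scenario:
    """Load a YAML (or JSON; YAML is a superset) scenario configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ScenarioValidationError(["top level: config must be a mapping"])
    return Scenario.from_dict(cfg)


def _assigned_value(assigned: Mapping[str, Any], key: str, light: str, default: float) -> float:
    val = assigned.get(key, default)
    if isinstance(val, Mapping):
        return float(val.get(light, default))
    return float(val)


@dataclass
class ScenarioResult:
    """Per-setting component table plus the yearly expected loss."""

    table: pd.DataFrame
    yearly_n_tm: float
    n_tot: Optional[float]


def run_scenario(scenario: Scenario, seed: Optional[int] = None) -> ScenarioResult:
    """Resolve all components for every setting and aggregate the yearly loss.

    Per-setting component overrides take precedence; the joint exposure
    ``p_op`` beats separate ``p_p * p_o``.  Below the turbine's cut-in speed
    the rotor is parked: hazard zone and blade incident are zero.
    Deterministic for a fixed seed (the seed drives the avoidance Monte
    Carlo; ``seed`` argument overrides the scenario's own).
    """
    sc = scenario
    seed = sc.seed if seed is None else seed
    area = exposure.rotor_swept_area(sc.turbine.diameter)
    n_tot = sc.population.n_tot if sc.population is not None else None
    rows = []
    for i, s in enumerate(sc.settings):
        ov = dict(s.get("overrides") or {})
        light = s["light"]
        v_c = float(s["current_speed"])
        hours = float(s.get("hours", 0.0))
        operating = v_c >= sc.turbine.cut_in and sc.turbine.rpm > 0

        # --- exposure: joint override > field activity > movement screen ---
        p_p = p_o = float("nan")
        if "p_op" in ov:
            p_op = float(ov["p_op"])
        elif s.get("activity_bin") in sc.activity and n_tot is not None:
            p_op = exposure.co_occurrence_rate(
                sc.activity[s["activity_bin"]], area, n_tot
            )
        else:
            if sc.population is None:
                raise ScenarioValidationError(
                    [f"{s.get('label', i)}: no exposure path — give overrides.p_op, "
                     "an activity_bin with population, or a population block with p_o override"]
                )
            p_p = float(ov.get("p_p", exposure.array_passage(sc.population)))
            p_o = float(ov.get("p_o", 1.0))
            p_op = p_p * p_o

        # --- avoidance failure ---
        if "p_a" in ov:
            p_a = float(ov["p_a"])
        elif sc.distributions:
            p_a = avoidance.monte_carlo_pa(
                sc.distributions, sc.turbine.diameter, max(v_c, 1e-6), light,
                sc.strategy, n_runs=sc.runs,
                seed=None if seed is None else seed + i,
            ).p_a
        else:
            raise ScenarioValidationError(
                [f"{s.get('label', i)}: no avoidance path — give overrides.p_a "
                 "or fish.distributions"]
            )

        # --- rotor geometry ---
        p_z = float(ov.get("p_z", rotor.hazard_zone(sc.turbine, v_c)))
        if "p_b" in ov:
            p_b = float(ov["p_b"]) if operating else 0.0
        elif operating and sc.traits:
            passage = rotor.passage_after_avoidance(
                sc.strategy, max(v_c, 1e-6),
                v_sust=float(sc.traits.get("v_sust", 0.0)),
                l_f=float(sc.traits.get("l_f", 0.0)),
                h_f=float(sc.traits.get("h_f", 0.0)),
            )
            p_b = rotor.blade_incident(sc.turbine, passage)
        else:
            p_b = 0.0

        # --- assigned injury components ---
        p_e = float(ov.get("p_e", _assigned_value(sc.assigned, "p_e", light, 0.0)))
        p_d = float(ov.get("p_d", _assigned_value(sc.assigned, "p_d", light, 0.0)))
        p_s = float(ov.get("p_s", _assigned_value(sc.assigned, "p_s", light, 0.0)))

        comp = risk_core.RiskComponents(
            p_a=p_a, p_z=p_z, p_s=p_s, p_b=p_b, p_e=p_e, p_d=p_d, p_op=p_op,
        )
        p_tm_exact = risk_core.turbine_mortality(comp, exact=True)
        p_tm_approx = risk_core.turbine_mortality(comp, exact=False)
        p_tm = p_tm_exact if sc.exact else p_tm_approx
        hourly = risk_core.expected_mortalities(p_tm, n_tot) if n_tot is not None else float("nan")
        rows.append(
            {
                "label": s.get("label", f"setting_{i}"),
                "current_speed": v_c,
                "light": light,
                "hours": hours,
                "p_op": p_op,
                "p_p": p_p,
                "p_o": p_o,
                "p_a": p_a,
                "p_z": p_z,
                "p_s": p_s,
                "p_b": p_b,
                "p_e": p_e,
                "p_d": p_d,
                "p_tm_exact": p_tm_exact,
                "p_tm_approx": p_tm_approx,
                "hourly_n_tm": hourly,
                "yearly_n_tm": hourly * hours if n_tot is not None else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    yearly = (
        risk_core.yearly_total(zip(table["hourly_n_tm"], table["hours"]))
        if n_tot is not None
        else float("nan")
    )
    total = {c: float("nan") for c in table.columns}
    total.update({"label": "TOTAL", "hours": float(table["hours"].sum()),
                  "yearly_n_tm": yearly})
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    return ScenarioResult(table=table, yearly_n_tm=yearly, n_tot=n_tot)


def write_report(result: ScenarioResult, csv_path=None) -> str:
    """Write the full-precision CSV (optional) and return a rounded text report."""
    if csv_path is not None:
        result.table.to_csv(csv_path, index=False)
    buf = io.StringIO()
    cols = ["label", "current_speed", "light", "hours", "p_op", "p_a", "p_z",
            "p_s", "p_b", "p_e", "p_d", "p_tm_exact", "hourly_n_tm", "yearly_n_tm"]
    disp = result.table[cols].copy()
    for c in cols:
        if disp[c].dtype.kind == "f":
            disp[c] = disp[c].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
    buf.write(disp.to_string(index=False))
    buf.write("\n")
    if result.n_tot is not None:
        buf.write(
            f"\nYearly expected turbine mortalities: {result.yearly_n_tm:.4g} "
            f"of a population of {result.n_tot:.0f}\n"
        )
    return buf.getvalue()
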