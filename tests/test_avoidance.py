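"""Avoidance-failure rules, Monte Carlo engine and sensitivity analysis."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tidalrisk.avoidance import (
    Encounter,
    FishTraits,
    TraitDistribution,
    default_trait_distributions,
    diverge_fails,
    monte_carlo_pa,
    realized_detection,
    reverse_fails,
    sample_entry_path,
    sensitivity_oat,
)
from tidalrisk.errors import ConfigError, DomainError


def traits(**kw):
    base = dict(l_f=0.4, v_b=2.0, v_sust=1.0, t_e=10.0, x_d_day=5.0)
    base.update(kw)
    return FishTraits(**base)


# ---------------------------------------------------------------------------
# Independent oracle: explicit small-timestep kinematic simulation
# ---------------------------------------------------------------------------

def brute_force_fails(strategy, x_r, x_d, v_c, v_b, t_e, alpha_deg, dt=1e-3):
    """Time-step the escape kinematics instead of solving for event times.

    The fish accrues transverse progress each step; 'diverge' fails when the
    current has carried it the detection gap downstream, 'reverse' when it is
    pushed back through the gap or exhausts, in either case before covering
    the required path.
    """
    if x_r <= 0:
        return False
    if v_b <= 0:
        return True
    a = math.radians(alpha_deg)
    trans = 0.0
    downstream = 0.0
    t = 0.0
    v_trans = v_b * math.sin(a) if strategy == "reverse" else v_b
    v_down = (v_c - v_b * math.cos(a)) if strategy == "reverse" else v_c
    while True:
        if trans >= x_r:
            return False
        if strategy == "reverse" and t >= t_e:
            return True
        if v_down > 0 and downstream >= x_d:
            return True
        t += dt
        trans += v_trans * dt
        if v_down > 0:
            downstream += v_down * dt


class TestDeterministicRules:
    def test_zero_required_path_is_safe(self):
        e = Encounter(x_r=0.0, x_d=5.0, v_c=3.0, rotor_diameter=20.0)
        assert not reverse_fails(e, traits())
        assert not diverge_fails(e, traits())

    def test_reverse_drift_branch_hand_evaluation(self):
        # drift time 5/(3 - 2 cos25) = 4.211 s < required 5/(2 sin25) = 5.916 s
        e = Encounter(x_r=5.0, x_d=5.0, v_c=3.0, rotor_diameter=20.0)
        assert reverse_fails(e, traits(v_b=2.0, t_e=10.0))

    def test_reverse_no_drift_branch_only_exhaustion(self):
        # v_b cos(25) = 3.63 > v_c = 2: no backward drift; required
        # 5/(4 sin25) = 2.96 s exceeds t_e = 1 s -> fail by exhaustion
        e = Encounter(x_r=5.0, x_d=5.0, v_c=2.0, rotor_diameter=20.0)
        assert reverse_fails(e, traits(v_b=4.0, t_e=1.0))
        # with ample endurance the same fish succeeds regardless of x_d
        assert not reverse_fails(e, traits(v_b=4.0, t_e=100.0, x_d_day=0.01))

    @pytest.mark.parametrize(
        "x_d,v_c,x_r,v_b,expect_fail",
        [(10, 2, 5, 2, False), (5, 3, 10, 1.5, True)],
    )
    def test_diverge_hand_evaluation(self, x_d, v_c, x_r, v_b, expect_fail):
        e = Encounter(x_r=x_r, x_d=x_d, v_c=v_c, rotor_diameter=20.0)
        assert diverge_fails(e, traits(v_b=v_b)) is expect_fail

    def test_zero_burst_speed_always_fails(self):
        e = Encounter(x_r=1.0, x_d=100.0, v_c=0.5, rotor_diameter=20.0)
        assert reverse_fails(e, traits(v_b=0.0))
        assert diverge_fails(e, traits(v_b=0.0))

    def test_rules_agree_with_kinematic_simulation(self):
        """Both closed-form rules match an explicit time-stepping simulation
        on 1000 randomized encounters (near-tie instances, where the margin
        is below the simulation resolution, are exempt)."""
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(1000):
            strategy = rng.choice(["reverse", "diverge"])
            x_r = rng.uniform(0.1, 9.0)
            x_d = rng.uniform(0.5, 10.0)
            v_c = rng.uniform(0.5, 3.0)
            v_b = rng.uniform(0.2, 4.0)
            t_e = rng.uniform(1.0, 30.0)
            alpha = rng.uniform(5.0, 80.0)
            e = Encounter(x_r=x_r, x_d=x_d, v_c=v_c, rotor_diameter=10.0)
            f = traits(v_b=v_b, t_e=t_e, alpha=alpha, x_d_day=x_d)
            rule = (reverse_fails if strategy == "reverse" else diverge_fails)(e, f)
            brute = brute_force_fails(strategy, x_r, x_d, v_c, v_b, t_e, alpha)
            if rule != brute:
                # disagreement allowed only within the time-step resolution
                a = math.radians(alpha)
                if strategy == "reverse":
                    v_trans = v_b * math.sin(a)
                    drift = v_c - v_b * math.cos(a)
                    avail = min(t_e, x_d / drift) if drift > 0 else t_e
                else:
                    v_trans = v_b
                    avail = x_d / v_c
                margin = abs(avail - x_r / v_trans)
                assert margin < 0.05, (
                    f"{strategy}: rule={rule} brute={brute} margin={margin}"
                )
            else:
                n_checked += 1
        assert n_checked > 950  # near-ties must be rare


class TestDetectionAndGeometry:
    @pytest.mark.parametrize(
        "light,factor,expected", [("daylight", 0.1, 10.0), ("lowlight", 0.1, 1.0),
                                  ("lowlight", 1.0, 10.0)]
    )
    def test_realized_detection(self, light, factor, expected):
        f = traits(x_d_day=10.0, lowlight_factor=factor)
        assert realized_detection(f, light) == pytest.approx(expected)

    def test_entry_path_bounds_and_extremes(self, rng):
        x_r = sample_entry_path(20.0, rng, size=50_000)
        assert np.all(x_r >= 0)
        assert np.all(x_r <= 10.0 + 1e-9)  # never beyond the hub half-chord

    def test_entry_path_mean_matches_numeric_integration(self, rng):
        """MC mean of x_r agrees with brute-force area integration of the
        nearer-edge chord distance over the uniform disc."""
        radius = 10.0
        # grid integration of (half_chord - |x|) over the disc
        n = 2001
        xs = np.linspace(-radius, radius, n)
        ys = np.linspace(-radius, radius, n)
        X, Y = np.meshgrid(xs, ys)
        inside = X**2 + Y**2 <= radius**2
        half_chord = np.sqrt(np.maximum(radius**2 - Y**2, 0.0))
        vals = (half_chord - np.abs(X))[inside]
        expected = vals.mean()
        draw = sample_entry_path(2 * radius, rng, size=400_000)
        se = draw.std(ddof=1) / math.sqrt(len(draw))
        assert abs(draw.mean() - expected) < 3 * se + 1e-2

    def test_uniform_entry_mode(self, rng):
        x_r = sample_entry_path(20.0, rng, size=20_000, mode="uniform")
        assert x_r.max() > 10.5  # spans the full diameter, unlike disc mode
        assert 9.0 < x_r.mean() < 11.0


class TestTraitDistribution:
    def test_point_mass(self, rng):
        d = TraitDistribution("v_b", "point", (2.5,))
        assert np.all(d.sample(100, rng) == 2.5)

    def test_truncation_respected(self, rng):
        d = TraitDistribution("t_e", "normal", (10.0, 5.0), bounds=(8.0, 12.0))
        x = d.sample(10_000, rng)
        assert x.min() >= 8.0 and x.max() <= 12.0

    def test_nonnegative_even_unbounded(self, rng):
        d = TraitDistribution("x_d", "normal", (0.5, 2.0))
        assert d.sample(10_000, rng).min() >= 0.0

    def test_infeasible_truncation(self, rng):
        d = TraitDistribution("v_b", "normal", (0.0, 0.01), bounds=(100.0, 200.0))
        with pytest.raises(ConfigError):
            d.sample(100, rng)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            TraitDistribution("v_b", "beta", (1.0, 1.0))


class TestMonteCarlo:
    def test_degenerate_always_fail(self):
        dists = {
            "x_r": TraitDistribution("x_r", "point", (10.0,)),
            "x_d": TraitDistribution("x_d", "point", (0.0,)),
            "v_b": TraitDistribution("v_b", "point", (0.5,)),
        }
        res = monte_carlo_pa(dists, 20.0, 2.0, "daylight", "diverge", 1000, seed=0)
        assert res.p_a == 1.0

    def test_closed_form_diverge(self, closed_form_diverge_dists):
        res = monte_carlo_pa(
            closed_form_diverge_dists, 20.0, 2.0, "daylight", "diverge",
            100_000, seed=3,
        )
        assert abs(res.p_a - 0.75) < 3 * res.se
        assert res.se == pytest.approx(
            math.sqrt(res.p_a * (1 - res.p_a) / res.n_runs)
        )

    def test_fixed_seed_bit_identical(self):
        dists = default_trait_distributions("trevally")
        a = monte_carlo_pa(dists, 20.0, 2.0, "lowlight", "reverse", 5000, seed=11)
        b = monte_carlo_pa(dists, 20.0, 2.0, "lowlight", "reverse", 5000, seed=11)
        assert a.p_a == b.p_a

    def test_empty_distributions_rejected(self):
        with pytest.raises(ConfigError):
            monte_carlo_pa({}, 20.0, 2.0, "daylight", "diverge", 100, seed=0)

    @pytest.mark.parametrize("strategy", ["reverse", "diverge"])
    def test_monotonicity_paired_seeds(self, strategy):
        """P_a rises with rotor diameter, current and darkness, and falls
        with burst speed and detection distance (paired random numbers)."""
        dists = {
            "v_b": TraitDistribution("v_b", "lognormal", (math.log(2.0), 0.4)),
            "t_e": TraitDistribution("t_e", "lognormal", (math.log(20.0), 0.5)),
            "x_d": TraitDistribution("x_d", "triangular", (1.0, 4.0, 8.0)),
        }
        n, seed = 10_000, 5

        def pa(d=20.0, v_c=2.0, light="daylight", dd=None):
            return monte_carlo_pa(
                dd or dists, d, v_c, light, strategy, n, seed=seed
            ).p_a

        base = pa()
        assert pa(d=5.0) <= base
        assert pa(v_c=3.0) >= base
        assert pa(light="lowlight") >= base
        faster = dict(dists, v_b=TraitDistribution("v_b", "lognormal",
                                                   (math.log(3.0), 0.4)))
        assert pa(dd=faster) <= base
        sharper = dict(dists, x_d=TraitDistribution("x_d", "triangular",
                                                    (2.0, 8.0, 16.0)))
        assert pa(dd=sharper) <= base


class TestSensitivity:
    def test_unread_parameter_changes_nothing(self, closed_form_diverge_dists):
        tab = sensitivity_oat(
            closed_form_diverge_dists, ["t_e", "alpha"],
            rotor_diameter=20.0, v_c=2.0, strategy="diverge",
            n_runs=20_000, seed=2,
        )
        assert (tab["pct_change"] == 0.0).all()

    def test_burst_speed_closed_form(self, closed_form_diverge_dists):
        # +50% v_b moves the failure threshold from x_r > 5 to x_r > 7.5:
        # P_a 0.75 -> 0.625, a -16.7% proportional change
        tab = sensitivity_oat(
            closed_form_diverge_dists, ["v_b"],
            rotor_diameter=20.0, v_c=2.0, strategy="diverge",
            n_runs=100_000, seed=2,
        )
        up = tab[(tab.parameter == "v_b") & (tab.direction == "+50%")]
        assert up["pct_change"].iloc[0] == pytest.approx(-16.67, abs=1.5)

    def test_zero_base_flagged_not_raised(self):
        dists = {
            "x_r": TraitDistribution("x_r", "point", (1.0,)),
            "x_d": TraitDistribution("x_d", "point", (100.0,)),
            "v_b": TraitDistribution("v_b", "point", (5.0,)),
        }
        tab = sensitivity_oat(dists, ["v_b"], rotor_diameter=20.0, v_c=2.0,
                              strategy="diverge", n_runs=1000, seed=0)
        assert tab["undefined"].all()
        assert tab["pct_change"].isna().all()

    def test_common_random_numbers_base_stable(self, closed_form_diverge_dists):
        t1 = sensitivity_oat(closed_form_diverge_dists, ["v_b"], rotor_diameter=20.0,
                             v_c=2.0, strategy="diverge", n_runs=5000, seed=9)
        t2 = sensitivity_oat(closed_form_diverge_dists, ["v_b"], rotor_diameter=20.0,
                             v_c=2.0, strategy="diverge", n_runs=5000, seed=9)
        assert t1.attrs["base_p_a"] == t2.attrs["base_p_a"]
        assert (t1["p_a"] == t2["p_a"]).all()


class TestTraitValidation:
    def test_bad_alpha(self):
        with pytest.raises(DomainError):
            traits(alpha=0.0)
        with pytest.raises(DomainError):
            traits(alpha=95.0)

    def test_bad_strategy(self):
        with pytest.raises(DomainError):
            traits(strategy="flee")

    def test_encounter_geometry_bounds(self):
        with pytest.raises(DomainError):
            Encounter(x_r=25.0, x_d=5.0, v_c=2.0, rotor_diameter=20.0)
        with pytest.raises(DomainError):
            Encounter(x_r=5.0, x_d=5.0, v_c=0.0, rotor_diameter=20.0)
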