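import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def closed_form_diverge_dists():
    """Trait set with a closed-form failure probability.

    'diverge' fails iff x_d/v_c < x_r/v_b; with x_r ~ U[0, 20], x_d = 10,
    v_b = 1 and v_c = 2 the failure set is x_r > 5, so P_a = 0.75 exactly.
    """
    from tidalrisk.avoidance import TraitDistribution

    return {
        "x_r": TraitDistribution("x_r", "uniform", (0.0, 20.0)),
        "x_d": TraitDistribution("x_d", "point", (10.0,)),
        "v_b": TraitDistribution("v_b", "point", (1.0,)),
    }


@pytest.fixture
def table4_scenario_config():
    """Six-setting scenario mirroring a published worked implementation,
    with the per-setting component values injected as fixed overrides."""
    day_settings = [
        ("day <0.75", 0.4, "daylight", dict(p_op=1.77e-3, p_a=0.02, p_e=0.0, p_d=0.0)),
        ("day 0.75-1.5", 1.1, "daylight",
         dict(p_op=2.22e-3, p_a=0.28, p_z=0.65, p_b=0.03, p_e=0.50, p_d=0.75)),
        ("day >1.5", 2.0, "daylight",
         dict(p_op=4.19e-5, p_a=0.49, p_z=0.65, p_b=0.02, p_e=0.50, p_d=0.75)),
        ("night <0.75", 0.4, "lowlight", dict(p_op=1.77e-3, p_a=0.72, p_e=0.0, p_d=0.0)),
        ("night 0.75-1.5", 1.1, "lowlight",
         dict(p_op=2.22e-3, p_a=0.90, p_z=0.65, p_b=0.03, p_e=0.75, p_d=0.75)),
        ("night >1.5", 2.0, "lowlight",
         dict(p_op=4.19e-5, p_a=0.94, p_z=0.65, p_b=0.02, p_e=0.75, p_d=0.75)),
    ]
    return {
        "turbine": {"diameter": 20, "n_blades": 2, "rpm": 14, "cut_in": 0.75},
        "population": {"n_tot": 10000, "v_p": 5, "r_p": 30},
        "fish": {"strategy": "diverge", "traits": {"l_f": 0.4, "v_sust": 1.0}},
        "assigned": {"p_s": 0.0},
        "run": {"runs": 1000, "seed": 7},
        "settings": [
            {"label": lab, "current_speed": v, "light": light, "hours": 1460,
             "overrides": ov}
            for lab, v, light, ov in day_settings
        ],
    }
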