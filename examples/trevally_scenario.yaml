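# A hypothetical single 20 m tidal turbine in a semidiurnal channel,
# assessed for a local population of 10 000 brassy trevally.
#
# Exposure (p_op = P_o x P_p) per current bin comes from standardized
# field-observed activity; avoidance failure (p_a) from the 'diverge'
# Monte Carlo model is injected per setting as a fixed value here so the
# run is instant and auditable. Evasion/damage/stress are assigned.
turbine:
  diameter: 20
  n_blades: 2
  rpm: 14
  cut_in: 0.75
  v_safe_blade: 5.0
  f_outer: 0.10
population:
  n_tot: 10000
  v_p: 5
  r_p: 30
fish:
  strategy: diverge
  traits:
    l_f: 0.4
    h_f: 0.08
    v_sust: 1.0
assigned:
  p_e: {daylight: 0.50, lowlight: 0.75}
  p_d: 0.75
  p_s: 0.0
run:
  runs: 100000
  seed: 1
  exact: true
settings:
  - {label: "day <0.75",      current_speed: 0.4, light: daylight, hours: 1460,
     overrides: {p_op: 1.77e-3, p_a: 0.02}}
  - {label: "day 0.75-1.5",   current_speed: 1.1, light: daylight, hours: 1460,
     overrides: {p_op: 2.22e-3, p_a: 0.28, p_b: 0.03}}
  - {label: "day >1.5",       current_speed: 2.0, light: daylight, hours: 1460,
     overrides: {p_op: 4.19e-5, p_a: 0.49, p_b: 0.02}}
  - {label: "night <0.75",    current_speed: 0.4, light: lowlight, hours: 1460,
     overrides: {p_op: 1.77e-3, p_a: 0.72}}
  - {label: "night 0.75-1.5", current_speed: 1.1, light: lowlight, hours: 1460,
     overrides: {p_op: 2.22e-3, p_a: 0.90, p_b: 0.03}}
  - {label: "night >1.5",     current_speed: 2.0, light: lowlight, hours: 1460,
     overrides: {p_op: 4.19e-5, p_a: 0.94, p_b: 0.02}}
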