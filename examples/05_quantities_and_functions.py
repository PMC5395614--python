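"""Quantity parsing, unit conversion, and stored fitted functions.

Shows the measurement layer on the worked examples: a published
conductance density string, an areal-to-volumetric density conversion,
and a Boltzmann steady-state inactivation curve evaluated from its
stored expression — which equals 0.5 at V = V_half by construction.
"""

from litanno import FunctionDesc, ValuesSimple
from litanno.measure import (area_to_volume_density, convert,
                             evaluate_function, parse_quantity, quantity)

# Published values are transcribed verbatim; only the unit is canonicalized.
g = parse_quantity("5 pS/μm^2")
print(f"parsed: {g}  (equals {convert(g, 'S/m^2')})")

# Stereology: 50,000 cells/mm^2 counted on a 25 um slice.
d3 = area_to_volume_density(quantity(50000, "mm^-2"), quantity(25, "um"))
print(f"areal 50000 mm^-2 on a 25 um slice -> {d3}")

# A fitted Boltzmann inactivation curve, stored as a safe expression.
boltzmann = FunctionDesc(
    expression="1/(1+exp((V-V_half)/k))",
    dependent_name="f",
    independent_names=("V",),
    fitted_parameters=(("V_half", ValuesSimple((-81.0,), "mV")),
                       ("k", ValuesSimple((6.4,), "mV"))),
)
for v in (-100.0, -81.0, -60.0):
    f = evaluate_function(boltzmann, {"V": v})
    print(f"f({v:6.1f} mV) = {f:.4f}")
# f at V = V_half is exactly 0.5: the half-inactivation potential.
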