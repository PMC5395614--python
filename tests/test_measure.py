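"""Quantities: parsing, conversion, densities, compounds, traces, functions."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from litanno.measure import (DimensionError, ExpressionError, UnitError,
                             area_to_volume_density, convert, evaluate_function,
                             free_symbols, interpolate_trace, parse_quantity,
                             parse_unit, quantity, reduce_compound)
from litanno.model import (DependentAxis, FunctionDesc, NumericalTraceDesc,
                           TraceAxis, ValuesCompound, ValuesSimple)


def simple(mags, unit="", stat="raw"):
    return ValuesSimple(tuple(float(m) for m in mags), unit, stat)


LI_INPUT_RESISTANCE = ValuesCompound((
    simple([55.0], "Mohm", "mean"),
    simple([19.0], "Mohm", "sem"),
    simple([94.0], "", "sample_size"),
))

LI_SPIKE_AMPLITUDE = ValuesCompound((
    simple([64.0], "mV", "mean"),
    simple([7.0], "mV", "sem"),
    simple([80.0], "", "sample_size"),
))


# --- parsing ---------------------------------------------------------------

def test_peak_conductance_density_parses_with_magnitude_untouched():
    q = parse_quantity("5 pS/μm^2")
    assert q.magnitudes == (5.0,)
    # pS/µm² is dimensionally siemens per square metre
    assert q.unit.dimension == parse_unit("S/m^2").dimension
    assert q.unit.scale == pytest.approx(1.0)  # 1 pS/um^2 == 1 S/m^2


def test_resting_potential_with_unicode_minus():
    q = parse_quantity("−60 mV")
    assert q.magnitudes == (-60.0,)
    assert q.unit.dimension == parse_unit("V").dimension
    assert q.unit.scale == pytest.approx(1e-3)


def test_unparseable_quantity_names_the_token():
    with pytest.raises(UnitError):
        parse_quantity("banana")
    with pytest.raises(UnitError, match="wibble"):
        parse_quantity("3 wibble")


@pytest.mark.parametrize("a,b", [
    ("um^2", "μm**2"), ("µm", "um"), ("mm⁻³", "mm^-3"),
    ("MΩ", "Mohm"), ("pS/um^2", "pS*um^-2"),
])
def test_unit_spelling_synonyms_are_canonicalized(a, b):
    ua, ub = parse_unit(a), parse_unit(b)
    assert ua.dimension == ub.dimension
    assert ua.scale == pytest.approx(ub.scale, rel=1e-15)


# --- conversion ------------------------------------------------------------

def test_inverse_cubic_micron_to_inverse_cubic_millimetre():
    q = convert(quantity(1.0, "um^-3"), "mm^-3")
    assert q.magnitude == pytest.approx(1e9, rel=1e-12)


def test_convert_round_trip_error_below_1e12_relative():
    q = quantity(37.5, "pS/um^2")
    back = convert(convert(q, "S/m^2"), "pS/um^2")
    assert back.magnitude == pytest.approx(37.5, rel=1e-12)


def test_dimension_mismatch_states_both_dimensions():
    with pytest.raises(DimensionError, match="dim"):
        convert(quantity(1, "mm^-2"), "mm^-3")


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.sampled_from(["m", "mm", "um", "nm", "km", "cm"]),
       st.sampled_from(["m", "mm", "um", "nm", "km", "cm"]),
       st.sampled_from(["m", "mm", "um", "nm", "km", "cm"]),
       st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
def test_conversion_is_transitive_across_prefix_chains(a, b, c, x):
    q = quantity(x, a)
    via = convert(convert(q, b), c)
    direct = convert(q, c)
    assert via.magnitude == pytest.approx(direct.magnitude, rel=1e-12)


# --- area -> volume density ------------------------------------------------

def test_simple_division_of_density_by_thickness():
    q = area_to_volume_density(quantity(1000, "mm^-2"), quantity(0.1, "mm"))
    assert q.magnitude == pytest.approx(10000.0, rel=1e-12)
    assert str(q.unit) == "mm^-3"


def test_micron_thickness_is_converted_before_dividing():
    # oracle: 25 um = 0.025 mm; 50000 / 0.025 = 2,000,000
    q = area_to_volume_density(quantity(50000, "mm^-2"), quantity(25, "um"))
    assert q.magnitude == pytest.approx(2_000_000.0, rel=1e-12)


def test_zero_or_negative_thickness_rejected():
    with pytest.raises(ValueError):
        area_to_volume_density(quantity(1000, "mm^-2"), quantity(0, "mm"))
    with pytest.raises(ValueError):
        area_to_volume_density(quantity(1000, "mm^-2"), quantity(-1, "um"))


def test_wrong_dimensions_rejected():
    with pytest.raises(DimensionError):
        area_to_volume_density(quantity(1000, "mm^-3"), quantity(1, "mm"))
    with pytest.raises(DimensionError):
        area_to_volume_density(quantity(1000, "mm^-2"), quantity(1, "s"))


def test_density_times_thickness_inverts_the_conversion():
    d2 = quantity(43210.0, "mm^-2")
    t = quantity(30, "um")
    d3 = area_to_volume_density(d2, t)
    t_mm = convert(t, "mm").magnitude
    assert d3.magnitude * t_mm == pytest.approx(d2.magnitude, rel=1e-12)


# --- compound reduction ----------------------------------------------------

def test_reduce_compound_recovers_published_mean_and_sample_size():
    mean = reduce_compound(LI_INPUT_RESISTANCE, "mean")
    assert mean.magnitudes == (55.0,) and mean.unit == "Mohm"
    n = reduce_compound(LI_INPUT_RESISTANCE, "sample_size")
    assert n.magnitudes == (94.0,)
    spike = reduce_compound(LI_SPIKE_AMPLITUDE, "mean")
    assert spike.magnitudes == (64.0,) and spike.unit == "mV"


def test_absent_role_error_lists_available_roles():
    with pytest.raises(KeyError) as err:
        reduce_compound(LI_INPUT_RESISTANCE, "median")
    msg = str(err.value)
    assert "mean" in msg and "sem" in msg and "sample_size" in msg


# --- trace interpolation ---------------------------------------------------

def density_trace(knots):
    xs = tuple(float(x) for x, _ in knots)
    ys = tuple(simple([y], "mm^-3") for _, y in knots)
    return NumericalTraceDesc(TraceAxis("animal_age", "day", xs),
                              DependentAxis("neuron_density", "mm^-3", ys))


def test_linear_midpoint_between_knots():
    t = density_trace([(7, 100), (21, 200)])
    q = interpolate_trace(t, quantity(14, "day"))
    assert q.magnitude == pytest.approx(150.0)
    assert q.unit.dimension == parse_unit("mm^-3").dimension


def test_exact_at_knots():
    t = density_trace([(7, 100), (14, 170), (21, 200)])
    for x, y in [(7, 100), (14, 170), (21, 200)]:
        assert interpolate_trace(t, quantity(x, "day")).magnitude == y


def test_extrapolation_refused():
    t = density_trace([(7, 100), (21, 200)])
    with pytest.raises(ValueError, match="extrapolation"):
        interpolate_trace(t, quantity(6, "day"))


def test_interpolation_point_unit_is_converted():
    t = density_trace([(7, 100), (21, 200)])
    two_weeks_in_hours = quantity(14 * 24, "h")
    assert interpolate_trace(t, two_weeks_in_hours).magnitude == pytest.approx(150.0)


def test_compound_dependent_values_reduce_to_mean_first():
    t = NumericalTraceDesc(
        TraceAxis("animal_age", "day", (7.0, 21.0)),
        DependentAxis("neuron_density", "mm^-3", (
            simple([100], "mm^-3"),
            ValuesCompound((simple([200], "mm^-3", "mean"),
                            simple([30], "mm^-3", "sem"),
                            simple([5], "", "sample_size"))),
        )))
    assert interpolate_trace(t, quantity(14, "day")).magnitude == pytest.approx(150.0)


def test_monotone_knots_give_monotone_interpolant():
    t = density_trace([(0, 10), (5, 20), (10, 80), (20, 90)])
    prev = -math.inf
    for i in range(41):
        y = interpolate_trace(t, quantity(i * 0.5, "day")).magnitude
        assert y >= prev
        prev = y


# --- function evaluation ---------------------------------------------------

def boltzmann(v_half=-81.0, k=6.4):
    return FunctionDesc(
        "1/(1+exp((V-V_half)/k))", "f", ("V",),
        (("V_half", simple([v_half], "mV")), ("k", simple([k], "mV"))))


def test_boltzmann_is_half_at_half_inactivation_potential():
    for v_half, k in [(-81.0, 6.4), (12.5, -3.0), (0.0, 7.0)]:
        assert evaluate_function(boltzmann(v_half, k), {"V": v_half}) == 0.5


def test_fitted_compound_parameters_contribute_their_mean():
    f = FunctionDesc(
        "1/(1+exp((V-V_half)/k))", "f", ("V",),
        (("V_half", ValuesCompound((simple([-81.0], "mV", "mean"),
                                    simple([2.0], "mV", "sem"),
                                    simple([12], "", "sample_size")))),
         ("k", simple([6.4], "mV"))))
    assert evaluate_function(f, {"V": -81.0}) == 0.5


def test_identity_expression():
    f = FunctionDesc("V", "f", ("V",), ())
    assert evaluate_function(f, {"V": 3}) == 3.0


def test_unbound_symbol_is_named():
    f = FunctionDesc("exp(x)", "f", (), ())
    with pytest.raises(ExpressionError, match="'x'"):
        evaluate_function(f, {})


@pytest.mark.parametrize("expr", [
    "import os", "__builtins__", "a；b", "sin(x)", "x!", "[1,2]", "a=b",
])
def test_disallowed_syntax_is_rejected(expr):
    f = FunctionDesc(expr, "f", ("x", "a", "b"), ())
    with pytest.raises(ExpressionError):
        evaluate_function(f, {"x": 1, "a": 1, "b": 1})


def test_power_and_function_calls():
    f = FunctionDesc("pow(x, 2) + x^3 - ln(exp(x))", "f", ("x",), ())
    assert evaluate_function(f, {"x": 2.0}) == pytest.approx(4 + 8 - 2)


def test_free_symbols_excludes_function_names():
    assert free_symbols("exp((V-V_half)/k)") == {"V", "V_half", "k"}


def _random_expression(rng, names, depth=0):
    """Independent oracle: build a random expression string while
    computing its value through plain Python arithmetic (a second code
    path, no shared parser)."""
    if depth > 3 or rng.random() < 0.3:
        if rng.random() < 0.5:
            v = round(rng.uniform(0.5, 4.0), 3)
            return repr(v), v
        name = rng.choice(list(names))
        return name, names[name]
    op = rng.choice(["+", "-", "*", "/", "neg", "exp", "pow"])
    a_s, a_v = _random_expression(rng, names, depth + 1)
    if op == "neg":
        return f"-({a_s})", -a_v
    if op == "exp":
        a_v = max(min(a_v, 5.0), -5.0)
        return f"exp({min(max(a_v, -5.0), 5.0)})", math.exp(a_v)
    if op == "pow":
        e = rng.choice([2, 3])
        return f"({a_s})^{e}", a_v ** e
    b_s, b_v = _random_expression(rng, names, depth + 1)
    if op == "/" and abs(b_v) < 1e-6:
        b_s, b_v = "1.0", 1.0
    ops = {"+": lambda: a_v + b_v, "-": lambda: a_v - b_v,
           "*": lambda: a_v * b_v, "/": lambda: a_v / b_v}
    val = ops[op]()
    return f"({a_s} {op} {b_s})", val


def test_evaluator_agrees_with_independent_arithmetic_oracle():
    rng = random.Random(2024)
    names = {"x": 1.7, "y": 0.9}
    for _ in range(100):
        expr, expected = _random_expression(rng, names)
        f = FunctionDesc(expr, "f", tuple(names), ())
        got = evaluate_function(f, names)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)
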