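"""Physical quantities for harmonizing curated experimental values.

Published values are transcribed exactly as printed and must never be
transformed in place; every operation here returns a *new* value, so the
curated record keeps the published magnitudes and unit while downstream
consumers obtain model-ready, dimensionally homogeneous numbers.

The unit system is a compact dimensional-analysis engine: each unit is a
product of SI-prefixed symbols with integer exponents, carrying a
seven-component dimension vector (m, kg, s, A, K, mol, cd) and a scale
factor to coherent SI. That covers the quantities that occur in
neurophysiological curation (conductance densities, potentials,
resistances, cell densities, slice thicknesses, ages) without pulling in a
general-purpose unit library.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Unit",
    "QuantityValue",
    "UnitError",
    "DimensionError",
    "ExpressionError",
    "parse_unit",
    "parse_quantity",
    "convert",
    "area_to_volume_density",
    "reduce_compound",
    "interpolate_trace",
    "evaluate_function",
    "parse_expression",
    "free_symbols",
]


class UnitError(ValueError):
    """A unit string could not be parsed."""


class DimensionError(ValueError):
    """Two quantities have incompatible physical dimensions."""


class ExpressionError(ValueError):
    """A stored function expression is malformed or uses forbidden syntax."""


# Dimension vectors are tuples over (m, kg, s, A, K, mol, cd).
_DIMLESS = (0, 0, 0, 0, 0, 0, 0)


def _dim(m=0, kg=0, s=0, A=0, K=0, mol=0, cd=0):
    return (m, kg, s, A, K, mol, cd)


# symbol -> (dimension vector, scale to coherent SI)
_BASE_UNITS: dict[str, tuple[tuple[int, ...], float]] = {
    "m": (_dim(m=1), 1.0),
    "g": (_dim(kg=1), 1e-3),
    "s": (_dim(s=1), 1.0),
    "A": (_dim(A=1), 1.0),
    "K": (_dim(K=1), 1.0),
    "mol": (_dim(mol=1), 1.0),
    "cd": (_dim(cd=1), 1.0),
    "Hz": (_dim(s=-1), 1.0),
    "N": (_dim(m=1, kg=1, s=-2), 1.0),
    "Pa": (_dim(m=-1, kg=1, s=-2), 1.0),
    "J": (_dim(m=2, kg=1, s=-2), 1.0),
    "W": (_dim(m=2, kg=1, s=-3), 1.0),
    "C": (_dim(s=1, A=1), 1.0),
    "V": (_dim(m=2, kg=1, s=-3, A=-1), 1.0),
    "F": (_dim(m=-2, kg=-1, s=4, A=2), 1.0),
    "ohm": (_dim(m=2, kg=1, s=-3, A=-2), 1.0),
    "S": (_dim(m=-2, kg=-1, s=3, A=2), 1.0),
    "L": (_dim(m=3), 1e-3),
    "min": (_dim(s=1), 60.0),
    "h": (_dim(s=1), 3600.0),
    "d": (_dim(s=1), 86400.0),
    "day": (_dim(s=1), 86400.0),
    "percent": (_DIMLESS, 0.01),
    "1": (_DIMLESS, 1.0),
}

_SYMBOL_ALIASES = {
    "Ω": "ohm",
    "Ohm": "ohm",
    "sec": "s",
    "days": "day",
    "hr": "h",
    "%": "percent",
    "": "1",
}

# SI prefixes; the micro prefix accepts "u", GREEK SMALL LETTER MU and
# MICRO SIGN spellings.
_PREFIXES = {
    "y": 1e-24, "z": 1e-21, "a": 1e-18, "f": 1e-15, "p": 1e-12,
    "n": 1e-9, "u": 1e-6, "m": 1e-3, "c": 1e-2, "d": 1e-1,
    "da": 1e1, "h": 1e2, "k": 1e3, "M": 1e6, "G": 1e9,
    "T": 1e12, "P": 1e15, "E": 1e18,
}

_SUPERSCRIPTS = str.maketrans("⁰¹²³⁴⁵⁶⁷⁸⁹⁻⁺", "0123456789-+")


def _resolve_symbol(sym: str) -> tuple[str, tuple[int, ...], float]:
    """Resolve one (possibly prefixed) unit symbol.

    Returns (canonical symbol, dimension, scale). Whole-symbol lookup wins
    over prefix splitting, so "min" is minutes rather than milli-inches.
    """
    sym = sym.replace("µ", "u").replace("μ", "u")
    sym = _SYMBOL_ALIASES.get(sym, sym)
    if sym in _BASE_UNITS:
        dim, scale = _BASE_UNITS[sym]
        return sym, dim, scale
    for plen in (2, 1):
        pref, rest = sym[:plen], sym[plen:]
        if pref in _PREFIXES and rest:
            rest = _SYMBOL_ALIASES.get(rest, rest)
            if rest in _BASE_UNITS:
                dim, scale = _BASE_UNITS[rest]
                return pref + rest, dim, scale * _PREFIXES[pref]
    raise UnitError(f"unknown unit symbol: {sym!r}")


@dataclass(frozen=True)
class Unit:
    """A product of prefixed unit symbols with integer exponents."""

    factors: tuple[tuple[str, int], ...]  # canonical symbol -> exponent
    dimension: tuple[int, ...]
    scale: float  # multiplicative factor to coherent SI

    def __str__(self) -> str:
        if not self.factors:
            return ""
        parts = []
        for sym, exp in self.factors:
            parts.append(sym if exp == 1 else f"{sym}^{exp}")
        return "*".join(parts)

    def __mul__(self, other: "Unit") -> "Unit":
        return _combine(self, other, +1)

    def __truediv__(self, other: "Unit") -> "Unit":
        return _combine(self, other, -1)

    @property
    def is_dimensionless(self) -> bool:
        return self.dimension == _DIMLESS


def _combine(a: Unit, b: Unit, sign: int) -> Unit:
    exps: dict[str, int] = dict(a.factors)
    for sym, exp in b.factors:
        exps[sym] = exps.get(sym, 0) + sign * exp
    factors = tuple((s, e) for s, e in exps.items() if e != 0)
    dim = tuple(da + sign * db for da, db in zip(a.dimension, b.dimension))
    scale = a.scale * (b.scale ** sign)
    return Unit(factors, dim, scale)


DIMENSIONLESS = Unit((), _DIMLESS, 1.0)

_FACTOR_RE = re.compile(
    r"^([A-Za-zµμΩ%]+|1)(?:\s*(?:\^|\*\*)?\s*\(?\s*([+-]?\d+)\s*\)?)?$"
)


def parse_unit(text: str) -> Unit:
    """Parse a unit string such as "pS/um^2", "mm⁻³" or "MΩ".

    Accepts "^" or "**" exponents, Unicode superscripts, "·" or "*" or
    whitespace products, "/" division, and µ/μ/u micro spellings.
    """
    if text is None:
        text = ""
    s = text.translate(_SUPERSCRIPTS)
    s = s.replace("**", "^").replace("−", "-")
    s = s.replace("·", "*").replace("×", "*").strip()
    if s in ("", "1"):
        return DIMENSIONLESS
    unit = DIMENSIONLESS
    sign = +1
    # split on / keeping the separators to track numerator vs denominator
    for chunk in re.split(r"(/)", s):
        chunk = chunk.strip()
        if chunk == "/":
            sign = -1
            continue
        if not chunk:
            continue
        for factor in re.split(r"[*\s]+", chunk):
            if not factor:
                continue
            m = _FACTOR_RE.match(factor)
            if m is None:
                # bare trailing exponent like "mm-3"
                m2 = re.match(r"^([A-Za-zµμΩ%]+?)(-?\d+)$", factor)
                if m2 is None:
                    raise UnitError(f"cannot parse unit token {factor!r} in {text!r}")
                sym_txt, exp_txt = m2.group(1), m2.group(2)
            else:
                sym_txt, exp_txt = m.group(1), m.group(2)
            exp = int(exp_txt) if exp_txt else 1
            sym, dim, scale = _resolve_symbol(sym_txt)
            e = sign * exp
            part = Unit(((sym, e),), tuple(d * e for d in dim), scale ** e)
            unit = unit * part
        # after the first "/", everything stays in the denominator
    return unit


@dataclass(frozen=True)
class QuantityValue:
    """One or more magnitudes sharing a single unit.

    Magnitudes are kept exactly as published; conversions return new
    instances.
    """

    magnitudes: tuple[float, ...]
    unit: Unit

    def __post_init__(self):
        if not self.magnitudes:
            raise ValueError("QuantityValue needs at least one magnitude")
        object.__setattr__(self, "magnitudes", tuple(float(x) for x in self.magnitudes))

    @property
    def magnitude(self) -> float:
        """The single magnitude; raises if there are several."""
        if len(self.magnitudes) != 1:
            raise ValueError("quantity holds multiple magnitudes")
        return self.magnitudes[0]

    def __str__(self) -> str:
        mags = ", ".join(repr(m) for m in self.magnitudes)
        u = str(self.unit)
        return f"{mags} {u}".strip()


def quantity(magnitudes: float | Sequence[float], unit: str | Unit) -> QuantityValue:
    """Convenience constructor from plain numbers and a unit string."""
    if isinstance(magnitudes, (int, float)):
        magnitudes = (float(magnitudes),)
    if isinstance(unit, str):
        unit = parse_unit(unit)
    return QuantityValue(tuple(magnitudes), unit)


_NUMBER_RE = re.compile(r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*)$")


def parse_quantity(text: str) -> QuantityValue:
    """Parse a published quantity string like "5 pS/μm^2" or "-60 mV".

    The magnitude is taken verbatim; only the unit spelling is
    canonicalized.
    """
    s = text.replace("−", "-").strip()
    m = _NUMBER_RE.match(s)
    if m is None:
        raise UnitError(f"no leading number in quantity string {text!r}")
    mag = float(m.group(1))
    unit = parse_unit(m.group(2))
    return QuantityValue((mag,), unit)


def convert(q: QuantityValue, target_unit: str | Unit) -> QuantityValue:
    """Re-express ``q`` in ``target_unit`` (dimensions must agree)."""
    tgt = parse_unit(target_unit) if isinstance(target_unit, str) else target_unit
    if q.unit.dimension != tgt.dimension:
        raise DimensionError(
            f"cannot convert {q.unit} (dim {q.unit.dimension}) "
            f"to {tgt} (dim {tgt.dimension})"
        )
    factor = q.unit.scale / tgt.scale
    return QuantityValue(tuple(m * factor for m in q.magnitudes), tgt)


def area_to_volume_density(d2: QuantityValue, thickness: QuantityValue) -> QuantityValue:
    """Convert an areal density (length⁻²) to a volumetric one (length⁻³).

    Stereological counts made on a slice of known thickness give surface
    densities; dividing by the slice thickness yields the volume density a
    model needs. The result is expressed with the same length symbol as
    the input density (e.g. mm⁻² with a 25 µm slice gives mm⁻³).
    """
    if d2.unit.dimension != _dim(m=-2):
        raise DimensionError(f"density must have dimension length^-2, got {d2.unit}")
    if thickness.unit.dimension != _dim(m=1):
        raise DimensionError(f"thickness must have dimension length, got {thickness.unit}")
    t = thickness.magnitude
    if t <= 0:
        raise ValueError(f"slice thickness must be positive, got {t}")
    # pick the length symbol carried by the density for a clean result unit
    length_syms = [sym for sym, exp in d2.unit.factors if exp == -2]
    if len(length_syms) == 1:
        target = parse_unit(f"{length_syms[0]}^-3")
    else:
        target = parse_unit("m^-3")
    length_unit = parse_unit(length_syms[0]) if len(length_syms) == 1 else parse_unit("m")
    t_conv = convert(thickness, length_unit).magnitude
    mags = tuple(m / t_conv for m in d2.magnitudes)
    return QuantityValue(mags, target)


def reduce_compound(compound, role: str):
    """Pick the single component of a compound value with the given
    statistic role (e.g. "mean" out of mean ± sem with sample size).

    Accepts a :class:`litanno.model.ValuesCompound`; returns its
    :class:`litanno.model.ValuesSimple` component.
    """
    matches = [c for c in compound.components if c.statistic == role]
    if not matches:
        roles = sorted({c.statistic for c in compound.components})
        raise KeyError(
            f"no component with statistic role {role!r}; available roles: "
            + "{" + ", ".join(roles) + "}"
        )
    return matches[0]


def _values_to_scalar(values) -> float:
    """Collapse a simple or compound value to one representative number.

    Simple values with repeated measures are averaged; compound values are
    reduced to their mean component first.
    """
    # imported lazily to avoid a cycle with litanno.model
    if hasattr(values, "components"):
        values = reduce_compound(values, "mean")
    return float(np.mean(values.magnitudes))


def interpolate_trace(trace, x: QuantityValue) -> QuantityValue:
    """Piecewise-linear interpolation of a numerical trace at ``x``.

    ``x`` is converted to the unit of the independent variable and must
    lie within the tabulated range — extrapolation beyond the published
    knots is refused. Compound dependent values are reduced to their mean
    component before interpolating. Exact at the knots.
    """
    ind_unit = parse_unit(trace.independent.unit)
    xi = convert(x, ind_unit).magnitude
    xs = np.asarray(trace.independent.magnitudes, dtype=float)
    ys = np.asarray([_values_to_scalar(v) for v in trace.dependent.values], dtype=float)
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    if xi < xs[0] or xi > xs[-1]:
        raise ValueError(
            f"interpolation point {xi} {ind_unit} outside trace range "
            f"[{xs[0]}, {xs[-1]}] — extrapolation refused"
        )
    yi = float(np.interp(xi, xs, ys))
    return QuantityValue((yi,), parse_unit(trace.dependent.unit))


# ---------------------------------------------------------------------------
# Restricted arithmetic expressions for stored fitted functions.
#
# Grammar: numbers, identifiers, + - * / , unary minus, parentheses,
# power ^ (or **), and calls to exp/log/ln/pow. Nothing else — stored
# expressions are evaluated without touching Python's eval.

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>\*\*|[+\-*/^(),]))"
)

_FUNCTIONS: dict[str, Callable[..., float]] = {
    "exp": math.exp,
    "log": math.log,
    "ln": math.log,
    "pow": math.pow,
}


def _tokenize(expression: str) -> list[tuple[str, str]]:
    s = expression.replace("−", "-")
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None or m.end() == pos:
            bad = s[pos:].strip()[:10]
            raise ExpressionError(f"disallowed token at {bad!r} in expression")
        if m.group("num") is not None:
            tokens.append(("num", m.group("num")))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name")))
        else:
            op = m.group("op")
            tokens.append(("op", "^" if op == "**" else op))
        pos = m.end()
    tokens.append(("end", ""))
    return tokens


# AST nodes: ("num", x) | ("var", name) | ("call", fname, [args]) |
# ("neg", node) | ("bin", op, left, right)


class _Parser:
    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def take(self, kind=None, value=None):
        tok = self.tokens[self.i]
        if (kind and tok[0] != kind) or (value and tok[1] != value):
            raise ExpressionError(f"unexpected token {tok[1]!r} (wanted {value or kind})")
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek()[0] != "end":
            raise ExpressionError(f"trailing input at {self.peek()[1]!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() in (("op", "+"), ("op", "-")):
            op = self.take()[1]
            node = ("bin", op, node, self.term())
        return node

    def term(self):
        node = self.unary()
        while self.peek() in (("op", "*"), ("op", "/")):
            op = self.take()[1]
            node = ("bin", op, node, self.unary())
        return node

    def unary(self):
        if self.peek() == ("op", "-"):
            self.take()
            return ("neg", self.unary())
        if self.peek() == ("op", "+"):
            self.take()
            return self.unary()
        return self.power()

    def power(self):
        base = self.atom()
        if self.peek() == ("op", "^"):
            self.take()
            return ("bin", "^", base, self.unary())  # right-associative
        return base

    def atom(self):
        kind, val = self.peek()
        if kind == "num":
            self.take()
            return ("num", float(val))
        if kind == "name":
            self.take()
            if self.peek() == ("op", "("):
                if val not in _FUNCTIONS:
                    raise ExpressionError(
                        f"function {val!r} not allowed (only {sorted(_FUNCTIONS)})"
                    )
                self.take(value="(")
                args = [self.expr()]
                while self.peek() == ("op", ","):
                    self.take()
                    args.append(self.expr())
                self.take(value=")")
                return ("call", val, args)
            return ("var", val)
        if (kind, val) == ("op", "("):
            self.take()
            node = self.expr()
            self.take(value=")")
            return node
        raise ExpressionError(f"unexpected token {val!r}")


def parse_expression(expression: str):
    """Parse a restricted arithmetic expression into an AST."""
    return _Parser(_tokenize(expression)).parse()


def free_symbols(expression: str) -> set[str]:
    """Variable names appearing in the expression (function names excluded)."""
    out: set[str] = set()

    def walk(node):
        tag = node[0]
        if tag == "var":
            out.add(node[1])
        elif tag == "neg":
            walk(node[1])
        elif tag == "bin":
            walk(node[2])
            walk(node[3])
        elif tag == "call":
            for a in node[2]:
                walk(a)

    walk(parse_expression(expression))
    return out


def _eval_node(node, env: Mapping[str, float]) -> float:
    tag = node[0]
    if tag == "num":
        return node[1]
    if tag == "var":
        if node[1] not in env:
            raise ExpressionError(f"unbound symbol {node[1]!r}")
        return float(env[node[1]])
    if tag == "neg":
        return -_eval_node(node[1], env)
    if tag == "call":
        return _FUNCTIONS[node[1]](*(_eval_node(a, env) for a in node[2]))
    op, left, right = node[1], node[2], node[3]
    a, b = _eval_node(left, env), _eval_node(right, env)
    if op == "+":
        return a + b
    if op == "-":
        return a - b
    if op == "*":
        return a * b
    if op == "/":
        return a / b
    if op == "^":
        return a ** b
    raise ExpressionError(f"unknown operator {op!r}")


def evaluate_function(f, bindings: Mapping[str, float]) -> float:
    """Evaluate a stored fitted function at the given independent values.

    Fitted parameters are taken from the function description itself
    (compound values contribute their mean component); ``bindings`` must
    cover every independent variable. The expression is interpreted under
    the restricted grammar — no general code evaluation.
    """
    env: dict[str, float] = {}
    for sym, values in f.fitted_parameters:
        env[sym] = _values_to_scalar(values)
    for sym, val in bindings.items():
        env[sym] = float(val)
    missing = free_symbols(f.expression) - set(env)
    if missing:
        raise ExpressionError(f"unbound symbol {sorted(missing)[0]!r}")
    return _eval_node(parse_expression(f.expression), env)
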