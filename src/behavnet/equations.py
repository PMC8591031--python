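"""Concise model definition from differential-equation strings with units.

Three pieces cooperate: a :class:`Clock` tracking physical time across
iterations, unit-carrying :class:`Quantity` values over the SI base
dimensions, and an equation parser turning text such as

    dv/dt = -v/tau : volt

into per-step forward-Euler updates ``x <- x + dt * rhs(x, t)`` evaluated
simultaneously for all ODEs (right-hand sides see pre-step values).  One
definition per line: ``d<name>/dt = <expr> : <unit>`` declares an ODE;
``<name> = <expr> : <unit>`` declares a derived quantity recomputed each step.
Unit tokens are ``second``/``s``, ``volt``/``V``, ``amp``/``A``, ``Hz`` and
``1`` (dimensionless), with power-of-ten prefixes (``ms``, ``mV``, ``nA``,
...).  Dimensional consistency is checked at parse time, so an equation set
that parses never raises a dimension error while stepping.  The reserved
symbol ``xi_uniform(a, b)`` draws fresh per-neuron noise each step from the
behaviour's child RNG stream.

Integration is forward Euler only — first-order accurate, which the
convergence test in the suite verifies directly.
"""
from __future__ import annotations

import ast
import re
from dataclasses import dataclass, field

import numpy as np

from .core import Behaviour, NetworkError

# dimension exponents over (metre, kilogram, second, ampere)
DIMENSIONLESS = (0, 0, 0, 0)
_SECOND = (0, 0, 1, 0)
_VOLT = (2, 1, -3, -1)
_AMP = (0, 0, 0, 1)
_HERTZ = (0, 0, -1, 0)

_DIM_NAMES = ("m", "kg", "s", "A")


class DimensionError(NetworkError):
    """Incompatible physical dimensions."""


class EquationError(NetworkError):
    """Unparseable equation text or an inconsistent equation set."""


def format_dims(dims) -> str:
    if all(e == 0 for e in dims):
        return "1"
    parts = [f"{n}^{e}" if e != 1 else n for n, e in zip(_DIM_NAMES, dims) if e != 0]
    return "*".join(parts)


class Quantity:
    """A magnitude with SI base-dimension exponents (time, voltage derived).

    Addition and subtraction require equal dimensions; multiplication and
    division add / subtract the exponent vectors.
    """

    __slots__ = ("magnitude", "dims")

    def __init__(self, magnitude, dims=DIMENSIONLESS):
        self.magnitude = magnitude
        self.dims = tuple(dims)

    def _coerce(self, other) -> "Quantity":
        if isinstance(other, Quantity):
            return other
        return Quantity(other, DIMENSIONLESS)

    def _require_same(self, other: "Quantity", op: str):
        if self.dims != other.dims:
            raise DimensionError(
                f"cannot {op} quantities of dimension {format_dims(self.dims)} "
                f"and {format_dims(other.dims)}")

    def __add__(self, other):
        other = self._coerce(other)
        self._require_same(other, "add")
        return Quantity(self.magnitude + other.magnitude, self.dims)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._coerce(other)
        self._require_same(other, "subtract")
        return Quantity(self.magnitude - other.magnitude, self.dims)

    def __rsub__(self, other):
        return self._coerce(other).__sub__(self)

    def __mul__(self, other):
        other = self._coerce(other)
        dims = tuple(a + b for a, b in zip(self.dims, other.dims))
        return Quantity(self.magnitude * other.magnitude, dims)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        dims = tuple(a - b for a, b in zip(self.dims, other.dims))
        return Quantity(self.magnitude / other.magnitude, dims)

    def __rtruediv__(self, other):
        return self._coerce(other).__truediv__(self)

    def __pow__(self, exponent):
        if isinstance(exponent, Quantity):
            if exponent.dims != DIMENSIONLESS:
                raise DimensionError("exponents must be dimensionless")
            exponent = exponent.magnitude
        if self.dims != DIMENSIONLESS and not float(exponent).is_integer():
            raise DimensionError("non-integer powers of dimensioned quantities")
        dims = tuple(int(e * exponent) for e in self.dims)
        return Quantity(self.magnitude ** exponent, dims)

    def __neg__(self):
        return Quantity(-self.magnitude, self.dims)

    def __pos__(self):
        return self

    def _cmp(self, other, op):
        other = self._coerce(other)
        self._require_same(other, "compare")
        return op(self.magnitude, other.magnitude)

    def __lt__(self, other):
        return self._cmp(other, lambda a, b: a < b)

    def __le__(self, other):
        return self._cmp(other, lambda a, b: a <= b)

    def __gt__(self, other):
        return self._cmp(other, lambda a, b: a > b)

    def __ge__(self, other):
        return self._cmp(other, lambda a, b: a >= b)

    def __eq__(self, other):
        other = self._coerce(other)
        return self.dims == other.dims and self.magnitude == other.magnitude

    def __hash__(self):
        return hash((self.magnitude, self.dims))

    def __repr__(self):
        return f"Quantity({self.magnitude!r}, {format_dims(self.dims)})"


_BASES = {
    "second": (1.0, _SECOND), "s": (1.0, _SECOND),
    "volt": (1.0, _VOLT), "V": (1.0, _VOLT),
    "amp": (1.0, _AMP), "ampere": (1.0, _AMP), "A": (1.0, _AMP),
    "Hz": (1.0, _HERTZ), "hertz": (1.0, _HERTZ),
}
_PREFIXES = {"p": 1e-12, "n": 1e-9, "u": 1e-6, "m": 1e-3, "": 1.0,
             "k": 1e3, "M": 1e6}

UNITS: dict[str, Quantity] = {"1": Quantity(1.0, DIMENSIONLESS)}
for _name, (_scale, _dims) in _BASES.items():
    for _p, _f in _PREFIXES.items():
        UNITS.setdefault(_p + _name, Quantity(_f * _scale, _dims))


def parse_unit(token: str) -> Quantity:
    """Parse a unit token, optionally a product/quotient like ``mV/ms``."""
    token = token.strip()
    m = re.fullmatch(r"([A-Za-z1]+)((?:\s*[*/]\s*[A-Za-z1]+)*)", token)
    if m is None:
        raise EquationError(f"malformed unit {token!r}")
    if m.group(1) not in UNITS:
        raise EquationError(
            f"unknown unit {m.group(1)!r}; known units include "
            "second, ms, volt, mV, amp, nA, Hz, 1")
    q = UNITS[m.group(1)]
    for op, name in re.findall(r"([*/])\s*([A-Za-z1]+)", m.group(2) or ""):
        if name not in UNITS:
            raise EquationError(f"unknown unit {name!r} in {token!r}")
        q = q * UNITS[name] if op == "*" else q / UNITS[name]
    return q


def parse_quantity(text) -> Quantity:
    """Parse ``"10*mV"``-style value strings (also accepts bare numbers)."""
    if isinstance(text, Quantity):
        return text
    if isinstance(text, (int, float)):
        return Quantity(float(text), DIMENSIONLESS)
    text = str(text).strip()
    m = re.fullmatch(r"([-+0-9.eE]+)\s*((?:[*/]\s*[A-Za-z1]+\s*)*)", text)
    if m is None:
        raise EquationError(f"malformed quantity {text!r} (expected e.g. '10*mV')")
    try:
        q = Quantity(float(m.group(1)), DIMENSIONLESS)
    except ValueError as exc:
        raise EquationError(f"malformed number in quantity {text!r}") from exc
    for op, name in re.findall(r"([*/])\s*([A-Za-z1]+)", m.group(2) or ""):
        if name not in UNITS:
            raise EquationError(f"unknown unit {name!r} in {text!r}")
        q = q * UNITS[name] if op == "*" else q / UNITS[name]
    return q


class Clock:
    """Physical time across iterations: ``t == iteration * dt``."""

    def __init__(self, dt="1*ms"):
        q = parse_quantity(dt)
        if q.dims not in (DIMENSIONLESS, _SECOND):
            raise EquationError(f"clock dt must be a time, got {format_dims(q.dims)}")
        self.dt = float(q.magnitude)       # seconds
        if self.dt <= 0:
            raise EquationError("clock dt must be positive")
        self.t = 0.0

    def advance(self):
        self.t += self.dt

    def reset(self):
        self.t = 0.0


_RESERVED_FUNCS = ("xi_uniform", "exp", "abs", "sqrt")

_ODE_RE = re.compile(r"^\s*d([A-Za-z_]\w*)\s*/\s*dt\s*=\s*(.+?)\s*:\s*(.+?)\s*$")
_DERIVED_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*=\s*(.+?)\s*:\s*(.+?)\s*$")

_ALLOWED_EQ_NODES = (
    ast.Expression, ast.Name, ast.Call, ast.Constant, ast.BinOp, ast.UnaryOp,
    ast.Compare, ast.Load,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.Mod,
    ast.USub, ast.UAdd,
    ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE,
)


@dataclass
class _Equation:
    name: str
    source: str
    code: object
    tree: ast.AST
    dims: tuple
    lineno: int


@dataclass
class EquationSet:
    """Parsed ODEs + derived quantities with SI-converted parameters.

    State vectors are stored as plain magnitudes in the SI unit of their
    declared dimension (volts, seconds, ...), so right-hand sides evaluate on
    raw numpy arrays at run time; all dimension checking happened at parse
    time.
    """

    odes: list[_Equation] = field(default_factory=list)
    derived: list[_Equation] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)
    parameter_dims: dict[str, tuple] = field(default_factory=dict)

    @property
    def state_names(self) -> list[str]:
        return [eq.name for eq in self.odes]

    def state_dims(self, name: str) -> tuple:
        for eq in self.odes:
            if eq.name == name:
                return eq.dims
        raise KeyError(name)


def _validate_expr(source: str, lineno: int) -> ast.AST:
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise EquationError(
            f"line {lineno}: syntax error in {source!r} at column {exc.offset}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_EQ_NODES):
            raise EquationError(
                f"line {lineno}: forbidden construct {type(node).__name__} in {source!r}")
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _RESERVED_FUNCS:
                raise EquationError(
                    f"line {lineno}: only {_RESERVED_FUNCS} may be called in equations")
    return tree


def _expr_names(tree: ast.AST) -> set[str]:
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)} - set(_RESERVED_FUNCS)


class _DimChecker:
    """Evaluate an expression tree on Quantity values to verify dimensions."""

    def __init__(self, env: dict[str, Quantity]):
        self.env = env

    def visit(self, node):
        if isinstance(node, ast.Expression):
            return self.visit(node.body)
        if isinstance(node, ast.Constant):
            return Quantity(float(node.value), DIMENSIONLESS)
        if isinstance(node, ast.Name):
            return self.env[node.id]
        if isinstance(node, ast.UnaryOp):
            v = self.visit(node.operand)
            return -v if isinstance(node.op, ast.USub) else v
        if isinstance(node, ast.BinOp):
            a, b = self.visit(node.left), self.visit(node.right)
            if isinstance(node.op, ast.Add):
                return a + b
            if isinstance(node.op, ast.Sub):
                return a - b
            if isinstance(node.op, ast.Mult):
                return a * b
            if isinstance(node.op, ast.Div):
                return a / b
            if isinstance(node.op, ast.Mod):
                a._require_same(b, "mod")
                return a
            if isinstance(node.op, ast.Pow):
                return a ** (b.magnitude if isinstance(b, Quantity) else b)
        if isinstance(node, ast.Compare):
            a = self.visit(node.left)
            for comp in node.comparators:
                a._require_same(self.visit(comp), "compare")
            return Quantity(1.0, DIMENSIONLESS)
        if isinstance(node, ast.Call):
            args = [self.visit(a) for a in node.args]
            fname = node.func.id
            if fname == "xi_uniform":
                return Quantity(1.0, DIMENSIONLESS)
            if fname in ("exp", "sqrt"):
                if args and args[0].dims != DIMENSIONLESS:
                    raise DimensionError(f"{fname}() requires a dimensionless argument")
                return Quantity(1.0, DIMENSIONLESS)
            if fname == "abs":
                return args[0]
        raise EquationError(f"cannot dimension-check node {type(node).__name__}")


def parse_equation_set(text: str, parameters: dict | None = None) -> EquationSet:
    """Parse equation text; check symbols and dimensions; compile the RHS code.

    Unresolved symbols across all equations are reported at once.  A dimension
    mismatch is rejected naming the offending equation and both dimensions.
    """
    eqset = EquationSet()
    for name, value in (parameters or {}).items():
        q = parse_quantity(value)
        eqset.parameters[name] = float(q.magnitude) if not isinstance(q.magnitude, np.ndarray) \
            else q.magnitude
        eqset.parameter_dims[name] = q.dims

    for lineno, raw in enumerate(str(text).splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _ODE_RE.match(line)
        if m:
            name, expr, unit = m.groups()
            tree = _validate_expr(expr, lineno)
            dims = parse_unit(unit).dims
            eqset.odes.append(_Equation(
                name, expr, compile(tree, f"<ode d{name}/dt>", "eval"), tree, dims, lineno))
            continue
        m = _DERIVED_RE.match(line)
        if m:
            name, expr, unit = m.groups()
            tree = _validate_expr(expr, lineno)
            dims = parse_unit(unit).dims
            eqset.derived.append(_Equation(
                name, expr, compile(tree, f"<derived {name}>", "eval"), tree, dims, lineno))
            continue
        raise EquationError(
            f"line {lineno}: cannot parse {raw!r} "
            "(expected 'd<name>/dt = <expr> : <unit>' or '<name> = <expr> : <unit>')")

    known = set(eqset.parameters) | {"t"} | set(UNITS) \
        | {eq.name for eq in eqset.odes} | {eq.name for eq in eqset.derived}
    unresolved = sorted(
        sym for eq in (*eqset.derived, *eqset.odes)
        for sym in _expr_names(eq.tree) - known)
    if unresolved:
        raise EquationError("unresolved symbols: " + ", ".join(sorted(set(unresolved))))

    # dimension check: states/params as unit quantities, t in seconds;
    # unit names themselves may appear in expressions (e.g. "y/second")
    env: dict[str, Quantity] = dict(UNITS)
    env.update({name: Quantity(1.0, dims) for name, dims in eqset.parameter_dims.items()})
    env.update({eq.name: Quantity(1.0, eq.dims) for eq in eqset.odes})
    env["t"] = Quantity(1.0, _SECOND)
    checker = _DimChecker(env)
    for eq in eqset.derived:
        got = checker.visit(eq.tree)
        if got.dims != eq.dims:
            raise EquationError(
                f"derived quantity {eq.name!r} (line {eq.lineno}): declared "
                f"{format_dims(eq.dims)} but expression has {format_dims(got.dims)}")
        env[eq.name] = Quantity(1.0, eq.dims)
    for eq in eqset.odes:
        want = tuple(a - b for a, b in zip(eq.dims, _SECOND))
        try:
            got = checker.visit(eq.tree)
        except DimensionError as exc:
            raise EquationError(f"equation d{eq.name}/dt (line {eq.lineno}): {exc}") from exc
        if got.dims != want:
            raise EquationError(
                f"equation d{eq.name}/dt (line {eq.lineno}): right-hand side has "
                f"dimension {format_dims(got.dims)} but needs "
                f"{format_dims(eq.dims)}/s = {format_dims(want)}")
    return eqset


def _runtime_env(eqset: EquationSet, state: dict, clock: Clock,
                 rng: np.random.Generator | None, size: int | None):
    def xi_uniform(a, b):
        if rng is None or size is None:
            raise EquationError("xi_uniform requires an RNG stream and a group size")
        return rng.uniform(a, b, size)

    env = {name: q.magnitude for name, q in UNITS.items()}
    env.update(eqset.parameters)
    env.update(state)
    env["t"] = clock.t
    env["xi_uniform"] = xi_uniform
    env["exp"] = np.exp
    env["abs"] = np.abs
    env["sqrt"] = np.sqrt
    return env


def euler_step(eqset: EquationSet, state: dict, clock: Clock,
               rng: np.random.Generator | None = None, size: int | None = None,
               iteration: int | None = None) -> dict:
    """One forward-Euler step, in place on ``state``.

    All right-hand sides are evaluated on pre-step values before any state is
    advanced (simultaneous-update semantics).  Derived quantities are
    recomputed first, also from pre-step state.  Raises on non-finite results,
    naming the state and iteration.
    """
    if not eqset.odes and not eqset.derived:
        return state
    env = _runtime_env(eqset, state, clock, rng, size)
    for eq in eqset.derived:
        env[eq.name] = eval(eq.code, {"__builtins__": {}}, env)
        state[eq.name] = env[eq.name]
    rhs = {}
    for eq in eqset.odes:
        value = eval(eq.code, {"__builtins__": {}}, env)
        if not np.all(np.isfinite(value)):
            where = f" at iteration {iteration}" if iteration is not None else ""
            raise EquationError(f"non-finite derivative for state {eq.name!r}{where}")
        rhs[eq.name] = value
    dt = clock.dt
    for eq in eqset.odes:
        state[eq.name] = state[eq.name] + dt * rhs[eq.name]
    return state


_RESET_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*=\s*(.+?)\s*$")


class EquationBehaviour(Behaviour):
    """Behaviour wrapper: equations + threshold + reset as one pipeline module.

    Each step integrates the equation set by one Euler step, evaluates the
    (optional) boolean ``threshold`` expression into the group's ``spike``
    vector, and applies the reset statements (``"v = 0"``, one per line or
    semicolon-separated) to the spiking neurons.  State vectors are registered
    on the parent group under their equation names, so recorders and other
    behaviours can read them.
    """

    def __init__(self, equations: str, parameters: dict | None = None,
                 threshold: str | None = None, reset: str | None = None,
                 init: dict | None = None, dt="1*ms", tag=None):
        super().__init__(tag=tag, equations=equations, parameters=parameters,
                         threshold=threshold, reset=reset, init=init, dt=dt)

    @property
    def writes(self):
        names = set(getattr(self, "eqset", EquationSet()).state_names)
        if self.init_params.get("threshold"):
            names.add("spike")
        return frozenset(names)

    reads = property(lambda self: frozenset(
        getattr(self, "eqset", EquationSet()).state_names))

    def set_variables(self, neurons):
        self.eqset = parse_equation_set(
            self.init_params["equations"], self.init_params.get("parameters"))
        self.clock = Clock(self.init_params.get("dt", "1*ms"))
        init = dict(self.init_params.get("init") or {})
        for name in self.eqset.state_names:
            value = init.pop(name, 0.0)
            if isinstance(value, (str, Quantity)) and not callable(value):
                try:
                    value = float(parse_quantity(value).magnitude)
                except EquationError:
                    pass                      # fall through to diversification spec
            neurons.new_state_vector(name, value)
        if init:
            raise EquationError(
                f"init values given for unknown states: {sorted(init)}")

        threshold = self.init_params.get("threshold")
        self._threshold_code = None
        if threshold:
            tree = _validate_expr(threshold, 0)
            unknown = _expr_names(tree) - set(self.eqset.state_names) \
                - set(self.eqset.parameters) - {"t"}
            if unknown:
                raise EquationError(
                    f"threshold references unknown symbols: {sorted(unknown)}")
            self._threshold_code = compile(tree, "<threshold>", "eval")
            neurons.register_state("spike", np.zeros(neurons.size, dtype=bool))

        self._resets = []
        reset = self.init_params.get("reset")
        if reset:
            for stmt in re.split(r"[;\n]", reset):
                stmt = stmt.strip()
                if not stmt:
                    continue
                m = _RESET_RE.match(stmt)
                if m is None:
                    raise EquationError(f"cannot parse reset statement {stmt!r}")
                name, expr = m.groups()
                if name not in self.eqset.state_names:
                    raise EquationError(
                        f"reset assigns to unknown state {name!r} "
                        f"(states: {self.eqset.state_names})")
                tree = _validate_expr(expr, 0)
                self._resets.append((name, compile(tree, f"<reset {name}>", "eval")))

    def new_iteration(self, neurons):
        self.clock.t = (neurons.network.iteration - 1) * self.clock.dt
        state = {name: neurons.state[name] for name in self.eqset.state_names}
        euler_step(self.eqset, state, self.clock, rng=self.rng, size=neurons.size,
                   iteration=neurons.network.iteration)
        for name in self.eqset.state_names:
            neurons.state[name] = state[name]
        if self._threshold_code is not None:
            env = _runtime_env(self.eqset, state, self.clock, self.rng, neurons.size)
            spike = np.asarray(
                eval(self._threshold_code, {"__builtins__": {}}, env), dtype=bool)
            neurons.spike = spike
            if spike.any():
                for name, code in self._resets:
                    value = eval(code, {"__builtins__": {}}, env)
                    arr = neurons.state[name]
                    arr[spike] = np.broadcast_to(value, (neurons.size,))[spike] \
                        if np.ndim(value) else value
                    neurons.state[name] = arr
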