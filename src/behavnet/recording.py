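"""Recorders: compiled expression strings that capture time series.

A :class:`Recorder` is an ordinary behaviour (give it a key larger than the
dynamics behaviours so it samples end-of-step state).  Each expression string
— e.g. ``"n.voltage"`` or ``"np.mean(n.voltage)"`` — is compiled once and
evaluated every ``interval``-th iteration in a sandboxed namespace exposing
only the aliases ``n`` (the parent group), ``np`` (a whitelist of numerical
reductions) and, on synapse groups, ``s``/``synapse``.  Recorded values are
deep-copied, so later mutation of live state never rewrites history.  The
expression source simultaneously acts as the tag under which the trace is
retrievable through the tagging system.
"""
from __future__ import annotations

import ast
import copy
import math

import numpy as np

from .core import Behaviour, NetworkError, NetworkObject, SynapseGroup


class ExpressionError(NetworkError):
    """Bad recorder/equation expression (unparseable or using forbidden names)."""


class RecordingError(NetworkError):
    """An expression failed while being evaluated during recording."""


_NUMPY_WHITELIST = (
    "mean", "sum", "max", "min", "std", "var", "median", "abs", "where", "clip",
    "any", "all", "count_nonzero", "argmax", "argmin", "sqrt", "exp", "log",
    "array", "concatenate",
)


class NumpyNamespace:
    """The ``np`` alias of the expression DSL: a fixed whitelist of functions."""

    def __getattr__(self, name):
        if name in _NUMPY_WHITELIST:
            return getattr(np, name)
        raise AttributeError(
            f"'np.{name}' is not available in recorder expressions; "
            "allowed: " + ", ".join(_NUMPY_WHITELIST))


NP_NAMESPACE = NumpyNamespace()

_ALLOWED_ALIASES = {"n", "np", "s", "synapse"}
_ALLOWED_NODES = (
    ast.Expression, ast.Name, ast.Attribute, ast.Call, ast.Constant, ast.BinOp,
    ast.UnaryOp, ast.Compare, ast.BoolOp, ast.Subscript, ast.Slice, ast.Tuple,
    ast.List, ast.keyword, ast.Load,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.FloorDiv, ast.Mod, ast.Pow,
    ast.USub, ast.UAdd, ast.Not, ast.Invert,
    ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE, ast.And, ast.Or,
)


class ExpressionProgram:
    """One compiled recorder expression; same source + same state => same value."""

    def __init__(self, source: str):
        self.source = source
        try:
            tree = ast.parse(source, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(
                f"cannot parse expression {source!r}: {exc.msg} (column {exc.offset})"
            ) from exc
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise ExpressionError(
                    f"expression {source!r} uses forbidden construct "
                    f"{type(node).__name__}")
            if isinstance(node, ast.Name) and node.id not in _ALLOWED_ALIASES:
                raise ExpressionError(
                    f"only the aliases {sorted(_ALLOWED_ALIASES)} resolve in "
                    f"expressions; {source!r} references {node.id!r}")
        self._code = compile(tree, f"<expression {source!r}>", "eval")

    def evaluate(self, context: dict):
        return eval(self._code, {"__builtins__": {}}, context)

    def state_reads(self) -> frozenset:
        """Names accessed as ``n.<name>`` — used for flow-chart dependency edges."""
        tree = ast.parse(self.source, mode="eval")
        return frozenset(
            node.attr for node in ast.walk(tree)
            if isinstance(node, ast.Attribute)
            and isinstance(node.value, ast.Name) and node.value.id in ("n", "s", "synapse"))


class Trace(NetworkObject):
    """Recorded time series of one expression, tagged by its source string."""

    def __init__(self, source: str):
        super().__init__(tag=None)
        self.tags = [source]
        self.source = source
        self.values: list = []

    def append(self, value):
        self.values.append(value)

    def __len__(self):
        return len(self.values)

    def __getitem__(self, item):
        if isinstance(item, str):           # keep tag-query semantics of the base class
            return super().__getitem__(item)
        return self.values[item]

    def __iter__(self):
        return iter(self.values)

    @property
    def np(self) -> np.ndarray:
        return np.array(self.values)


class Recorder(Behaviour):
    """Record expression values every ``interval``-th iteration.

    Recording happens at iterations where ``iteration % interval == 0``,
    counting iterations from 1, so ``interval=10`` over 100 steps yields
    record times 10, 20, ..., 100.  An optional ``transform`` callable
    post-processes every recorded value.
    """

    def __init__(self, *expressions: str, interval: int = 1, transform=None, tag=None):
        super().__init__(tag=tag, expressions=list(expressions), interval=interval)
        interval = int(interval)
        if interval < 1:
            raise NetworkError(f"recorder interval must be >= 1, got {interval}")
        self.expressions = list(expressions)
        self.interval = interval
        self.transform = transform
        self._entries: list[tuple[ExpressionProgram, object, Trace]] = []
        self.iteration_trace: list[int] = []

    @property
    def reads(self):  # dependency edges for the module graph
        names: set[str] = set()
        for prog, _, _ in self._entries:
            names |= prog.state_reads()
        return frozenset(names)

    def set_variables(self, parent):
        self._entries = []
        self.iteration_trace = []
        for source in self.expressions:
            self._add_entry(source, self.transform)

    def _add_entry(self, source: str, transform) -> Trace:
        trace = Trace(source)
        trace.network = self.network
        self._entries.append((ExpressionProgram(source), transform, trace))
        if self.network is not None:
            self.network._bump_structure()
        return trace

    @property
    def traces(self) -> dict:
        out: dict = {}
        for prog, _, trace in self._entries:
            out.setdefault(prog.source, trace)
        return out

    def _context(self, parent) -> dict:
        ctx = {"n": parent, "np": NP_NAMESPACE}
        if isinstance(parent, SynapseGroup):
            ctx["s"] = parent
            ctx["synapse"] = parent
        return ctx

    def new_iteration(self, parent):
        iteration = parent.network.iteration
        if iteration % self.interval != 0:
            return
        self.record_step(parent, iteration)

    def record_step(self, parent, iteration: int):
        """Evaluate each expression once and append deep-copied results."""
        ctx = self._context(parent)
        for prog, transform, trace in self._entries:
            try:
                value = prog.evaluate(ctx)
                if transform is not None:
                    value = transform(value)
            except Exception as exc:
                raise RecordingError(
                    f"expression {prog.source!r} failed at iteration {iteration}: {exc}"
                ) from exc
            if isinstance(value, np.ndarray):
                value = value.copy()
            elif not isinstance(value, (int, float, complex, bool, np.number, np.bool_)):
                value = copy.deepcopy(value)
            trace.append(value)
        self.iteration_trace.append(iteration)

    def _children(self):
        return [trace for _, _, trace in self._entries]


def merge_recorders(recorders: list[Recorder], key=None) -> Recorder:
    """Replace redundant recorders on one parent by a single covering recorder.

    The merged recorder records the union of expressions at the gcd of the
    intervals.  For an expression recorded by several of the inputs with the
    same transform, the longest existing trace is adopted, so tag-based
    retrieval keeps working on previously recorded history.  An identical
    expression with *different* transforms is kept as separate entries (no
    merge for that expression).
    """
    if not recorders:
        raise NetworkError("merge_recorders needs at least one recorder")
    parent = recorders[0].parent
    if parent is None:
        raise NetworkError("recorders must be attached to a network before merging")
    if any(r.parent is not parent for r in recorders):
        raise NetworkError("can only merge recorders sharing one parent group")
    net = parent.network

    interval = recorders[0].interval
    for r in recorders[1:]:
        interval = math.gcd(interval, r.interval)
    if key is None:
        key = max(r.key for r in recorders)

    merged = Recorder(interval=interval)
    groups: dict = {}
    order: list = []
    for r in recorders:
        for prog, transform, trace in r._entries:
            gkey = (prog.source, id(transform) if transform is not None else None)
            if gkey not in groups:
                groups[gkey] = (prog, transform, trace)
                order.append(gkey)
            elif len(trace) > len(groups[gkey][2]):
                groups[gkey] = (prog, transform, trace)
    merged._entries = [groups[g] for g in order]
    merged.expressions = [groups[g][0].source for g in order]
    merged.iteration_trace = max(
        (r.iteration_trace for r in recorders), key=len, default=[])

    for r in recorders:
        net._remove_behaviour(parent, r.key)
    merged._initialized = True          # entries already compiled and adopted
    was_live = net._entries is not None
    parent.behaviours[key] = merged
    merged.network = net
    if was_live:
        net._bind_behaviour(key, merged, parent)
        net._insert_entry(key, merged, parent)
    for _, _, trace in merged._entries:
        trace.network = net
    net._bump_structure()
    return merged
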