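"""Diversification strings: textual distribution specs for per-neuron parameters.

A scalar parameter such as ``leak_factor=0.9`` can be replaced by a string like
``"normal(0.9,0.1)"`` to give every neuron its own value drawn from that
distribution, without touching the model code.  The grammar is

    SPEC := NUMBER | NAME "(" ARGS ")" [";plot"]

where NAME is one of the supported numpy.random distributions and a bare
``"uniform"`` is shorthand for ``uniform(0,1)``.  The optional ``;plot`` suffix
is a request for a histogram preview; the simulation core parses and ignores it
(an export hook lives in the storage layer) and never opens windows.
Custom sampler callables ``f(rng, size) -> array`` are accepted as well.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from numbers import Number
from typing import Callable

import numpy as np

SUPPORTED_DISTRIBUTIONS = ("uniform", "normal", "lognormal", "poisson")

_CALL_RE = re.compile(r"^([A-Za-z_]\w*)\s*(?:\(\s*(.*?)\s*\))?$")


class DiversificationError(ValueError):
    """Raised for specs that do not follow the diversification grammar."""


@dataclass(frozen=True)
class ParsedSpec:
    kind: str                     # "constant" | "distribution" | "callable"
    value: float | None = None
    name: str | None = None
    args: tuple[float, ...] = ()
    func: Callable | None = None
    plot: bool = False

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, self.value, dtype=float)
        if self.kind == "callable":
            return np.asarray(self.func(rng, size), dtype=float)
        return np.asarray(getattr(rng, self.name)(*self.args, size=size), dtype=float)


def parse_spec(spec) -> ParsedSpec:
    """Parse a scalar, string, or callable into a :class:`ParsedSpec`."""
    if callable(spec):
        return ParsedSpec(kind="callable", func=spec)
    if isinstance(spec, Number):
        return ParsedSpec(kind="constant", value=float(spec))
    if not isinstance(spec, str):
        raise DiversificationError(
            f"cannot interpret {spec!r} as a diversification spec "
            "(expected number, string, or callable)")

    text = spec.strip()
    plot = False
    if text.endswith(";plot"):
        plot = True
        text = text[: -len(";plot")].strip()
    try:
        return ParsedSpec(kind="constant", value=float(text), plot=plot)
    except ValueError:
        pass

    m = _CALL_RE.match(text)
    if m is None:
        raise DiversificationError(f"malformed diversification spec: {spec!r}")
    name, argtext = m.group(1), m.group(2)
    if name not in SUPPORTED_DISTRIBUTIONS:
        raise DiversificationError(
            f"unknown distribution {name!r}; supported distributions are "
            + ", ".join(SUPPORTED_DISTRIBUTIONS))
    if argtext is None or argtext == "":
        args: tuple[float, ...] = (0.0, 1.0) if name == "uniform" else ()
    else:
        try:
            args = tuple(float(a) for a in argtext.split(","))
        except ValueError as exc:
            raise DiversificationError(
                f"non-numeric argument in diversification spec {spec!r}") from exc
    return ParsedSpec(kind="distribution", name=name, args=args, plot=plot)


def resolve_spec(spec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Turn a spec into a length-``size`` float vector (one draw per neuron)."""
    return parse_spec(spec).sample(rng, size)


def is_diversification_string(spec) -> bool:
    if not isinstance(spec, str):
        return False
    try:
        parse_spec(spec)
        return True
    except DiversificationError:
        return False
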