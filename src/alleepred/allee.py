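"""Allee-effect factors for the predator's numerical response.

The predator's per-capita reproduction is scaled by a dimensionless factor
``h(y)`` of the predator density ``y``.  A *strong* Allee effect is encoded
by five qualitative axioms:

A1. ``h(0) = 0`` — an isolated predator cannot reproduce;
A2. ``0 <= h(y) <= 1`` — ``h`` is the realised fraction of the maximal
    conversion efficiency;
A3. ``h'(y) > 0`` — reproduction improves with density (no interference);
A4. ``h''(y) <= 0`` — the improvement decelerates;
A5. ``h(y) -> 1`` as ``y -> infinity``.

Three classical saturating parameterisations are built in, all with the same
initial slope ``h'(0) = 1/delta`` so that ``delta`` is comparable across
forms: the Monod (hyperbolic) form ``y/(delta+y)``, the Ivlev (exponential)
form ``1-exp(-y/delta)`` and the hyperbolic tangent ``tanh(y/delta)``.
``delta`` sets the predator density at which the Allee effect is strongly
felt; ``delta -> 0`` recovers the Rosenzweig-MacArthur limit ``h == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "AlleeFunction",
    "AxiomReport",
    "make_allee",
    "verify_allee_axioms",
    "BUILTIN_ALLEE_NAMES",
]

BUILTIN_ALLEE_NAMES = ("monod", "ivlev", "tanh")

#: tolerance used when checking the saturation axiom A5 at the end of a grid
TOL_ASYM = 1e-3

_FD_STEP = 1e-6  # central finite-difference step for custom derivatives


@dataclass(frozen=True)
class AlleeFunction:
    """A saturating Allee factor ``h(y)`` with its first two derivatives.

    Attributes
    ----------
    name:
        ``"monod"``, ``"ivlev"``, ``"tanh"`` or ``"custom"``.
    delta:
        Allee intensity; for the built-ins, ``1/h'(0)``.
    value, d1, d2:
        Vectorised callables for ``h``, ``h'`` and ``h''`` on ``y >= 0``.
    """

    name: str
    delta: float
    value: Callable[[np.ndarray], np.ndarray]
    d1: Callable[[np.ndarray], np.ndarray]
    d2: Callable[[np.ndarray], np.ndarray]

    def __call__(self, y):
        return self.value(y)

    def inverse(self, c: float) -> float:
        """Solve ``h(y) = c`` for ``y`` (``0 < c < 1``).

        Closed forms for the built-ins; bisection for custom functions.
        """
        if not 0.0 < c < 1.0:
            raise ValueError(f"h is invertible only on (0, 1); got c={c}")
        d = self.delta
        if self.name == "monod":
            return d * c / (1.0 - c)
        if self.name == "ivlev":
            return -d * np.log(1.0 - c)
        if self.name == "tanh":
            return d * np.arctanh(c)
        from scipy.optimize import brentq

        hi = max(1.0, 10.0 * d)
        while self.value(hi) < c:
            hi *= 4.0
            if hi > 1e12:
                raise ValueError("h does not reach the requested level")
        return brentq(lambda y: self.value(y) - c, 0.0, hi, xtol=1e-14)


def _monod(delta: float) -> AlleeFunction:
    return AlleeFunction(
        "monod",
        delta,
        lambda y: np.asarray(y) / (delta + np.asarray(y)),
        lambda y: delta / (delta + np.asarray(y)) ** 2,
        lambda y: -2.0 * delta / (delta + np.asarray(y)) ** 3,
    )


def _ivlev(delta: float) -> AlleeFunction:
    return AlleeFunction(
        "ivlev",
        delta,
        lambda y: 1.0 - np.exp(-np.asarray(y) / delta),
        lambda y: np.exp(-np.asarray(y) / delta) / delta,
        lambda y: -np.exp(-np.asarray(y) / delta) / delta**2,
    )


def _tanh(delta: float) -> AlleeFunction:
    # clip the argument to keep cosh finite; tanh(350) == 1 in double
    z = lambda y: np.minimum(np.asarray(y) / delta, 350.0)
    return AlleeFunction(
        "tanh",
        delta,
        lambda y: np.tanh(z(y)),
        lambda y: 1.0 / np.cosh(z(y)) ** 2 / delta,
        lambda y: -2.0 * np.tanh(z(y)) / np.cosh(z(y)) ** 2 / delta**2,
    )


_BUILTINS = {"monod": _monod, "ivlev": _ivlev, "tanh": _tanh}


def make_allee(name: str, delta: float) -> AlleeFunction:
    """Return a built-in Allee factor by name.

    Parameters
    ----------
    name:
        One of ``"monod"``, ``"ivlev"``, ``"tanh"``.
    delta:
        Positive Allee intensity.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive; got {delta}")
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unsupported Allee parameterisation {name!r}; "
            f"choose from {BUILTIN_ALLEE_NAMES}"
        ) from None
    return factory(float(delta))


def make_custom_allee(
    value: Callable,
    delta: float,
    d1: Optional[Callable] = None,
    d2: Optional[Callable] = None,
    name: str = "custom",
) -> AlleeFunction:
    """Wrap a user-supplied ``h(y)``, with finite-difference derivative
    fallbacks (central, step ``1e-6``) when ``d1``/``d2`` are not given.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive; got {delta}")
    if d1 is None:
        def d1(y, _v=value):  # noqa: E306
            y = np.asarray(y, dtype=float)
            return (_v(y + _FD_STEP) - _v(np.maximum(y - _FD_STEP, 0.0))) / (
                _FD_STEP + np.minimum(y, _FD_STEP)
            )
    if d2 is None:
        def d2(y, _v=value):  # noqa: E306
            y = np.asarray(y, dtype=float)
            return (_v(y + _FD_STEP) - 2.0 * _v(y) + _v(np.abs(y - _FD_STEP))) / _FD_STEP**2
    return AlleeFunction(name, float(delta), value, d1, d2)


@dataclass
class AxiomReport:
    """Outcome of checking (A1)-(A5) on a grid; failures carry the first
    violating grid point."""

    passed: dict = field(default_factory=dict)
    first_violation: dict = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


def verify_allee_axioms(
    h: AlleeFunction,
    grid: Sequence[float],
    tol_asym: float = TOL_ASYM,
    upper: float = 1.0,
) -> AxiomReport:
    """Check the Allee axioms (A1)-(A5) for ``h`` on a grid.

    A1 is checked exactly at 0, A2-A4 at every grid point, and A5 as
    ``h(grid[-1]) >= upper - tol_asym``.  ``upper`` exists so that the
    structural-sensitivity study can relax saturation to ``1 + eps``.
    A4 is enforced as ``h'' <= 0`` (the tanh form has ``h''(0) = 0``).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty, sorted and start at 0")
    rep = AxiomReport()
    vals = np.asarray(h.value(grid), dtype=float)
    d1 = np.asarray(h.d1(grid), dtype=float)
    d2 = np.asarray(h.d2(grid), dtype=float)

    def record(key, ok_mask):
        ok = bool(np.all(ok_mask))
        rep.passed[key] = ok
        if not ok:
            rep.first_violation[key] = float(grid[np.argmin(ok_mask)])

    rep.passed["A1"] = bool(abs(vals[0]) < 1e-12)
    if not rep.passed["A1"]:
        rep.first_violation["A1"] = 0.0
    record("A2", (vals >= -1e-12) & (vals <= upper + 1e-12))
    # d1 may underflow to 0 where h is saturated to 1 in double precision
    record("A3", (d1 > 0.0) | (vals >= upper - 1e-12))
    record("A4", d2 <= 1e-12)
    rep.passed["A5"] = bool(vals[-1] >= upper - tol_asym)
    if not rep.passed["A5"]:
        rep.first_violation["A5"] = float(grid[-1])
    return rep


def standard_axiom_grid(delta: float, n: int = 512) -> np.ndarray:
    """Grid used by default for axiom checking: 0 plus log-spaced points up
    to ``1e4*delta``, where all built-ins (including the slowly saturating
    Monod form, ``1 - h = delta/(delta+y)``) reach 1 to within ``1e-3``."""
    return np.concatenate([[0.0], np.geomspace(1e-4 * delta, 1e4 * delta, n)])
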