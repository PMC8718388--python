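"""The dimensionless predator-prey vector field and its Jacobian.

The dimensional Gause model with logistic prey growth, a Holling type II
functional response ``g(N) = aN/(1+aqN)`` and an Allee factor ``psi(P)``
multiplying the predator's conversion efficiency ``e`` is reduced, via
``x = N/K``, ``y = P/(K r q)``, ``t = r T``, to

    dx/dt = x(1-x) - x y / (beta + x)
    dy/dt = alpha x y h(y) / (beta + x) - m y

with ``alpha = e/(qr)``, ``beta = 1/(aqK)`` and ``m = mu/r``.  ``h`` is the
dimensionless Allee factor (see :mod:`alleepred.allee`).  Both axes are
invariant; the biologically relevant state space is the closed first
quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allee import AlleeFunction

__all__ = ["ModelParams", "DimensionalParams", "State", "rhs", "jacobian",
           "nondimensionalise"]


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters (all strictly positive).

    ``alpha``: maximal predator production per unit prey intake;
    ``beta``: half-saturation prey density of the functional response
    (small ``beta`` = strongly saturating response, eutrophic environment);
    ``m``: predator mortality relative to prey growth.

    Interior equilibria additionally require ``alpha > m``, which is checked
    where it matters, not here.
    """

    alpha: float
    beta: float
    m: float

    def __post_init__(self):
        for name in ("alpha", "beta", "m"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive real; got {v}")


@dataclass(frozen=True)
class DimensionalParams:
    """Parameters of the dimensional model: prey growth rate ``r``,
    carrying capacity ``K``, attack rate ``a``, handling-time coefficient
    ``q``, conversion efficiency ``e`` in (0,1), predator mortality ``mu``.
    """

    r: float
    K: float
    a: float
    q: float
    e: float
    mu: float

    def __post_init__(self):
        for name in ("r", "K", "a", "q", "e", "mu"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive real; got {v}")
        if not self.e < 1:
            raise ValueError(f"e must lie in (0,1); got {self.e}")


@dataclass(frozen=True)
class State:
    """Dimensionless prey/predator densities; nonnegative."""

    x: float
    y: float

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ValueError(f"state must lie in the closed first quadrant; got {self}")

    def __iter__(self):
        yield self.x
        yield self.y


def nondimensionalise(d: DimensionalParams) -> ModelParams:
    """Map dimensional parameters to ``(alpha, beta, m)``.

    The predator density is scaled by ``K r q`` (the scaling that makes the
    dimensional equations collapse onto the dimensionless form above).
    """
    return ModelParams(alpha=d.e / (d.q * d.r), beta=1.0 / (d.a * d.q * d.K),
                       m=d.mu / d.r)


def rhs(s, p: ModelParams, h: AlleeFunction):
    """Vector field ``(dx/dt, dy/dt)`` at state ``s`` (a ``State`` or any
    ``(x, y)`` pair)."""
    x, y = s
    fr = x / (p.beta + x)
    return (x * (1.0 - x) - fr * y,
            p.alpha * fr * float(h.value(y)) * y - p.m * y)


def jacobian(s, p: ModelParams, h: AlleeFunction) -> np.ndarray:
    """Jacobian of the vector field at ``s`` (closed form)."""
    x, y = s
    b = p.beta
    hv = float(h.value(y))
    h1 = float(h.d1(y))
    J11 = 1.0 - 2.0 * x - y / (b + x) + x * y / (b + x) ** 2
    J12 = -x / (b + x)
    J21 = p.alpha * b * y * hv / (b + x) ** 2
    J22 = p.alpha * x / (b + x) * hv + p.alpha * x * y / (b + x) * h1 - p.m
    return np.array([[J11, J12], [J21, J22]])
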