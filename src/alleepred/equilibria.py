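"""Equilibria of the dimensionless model and their classification.

Besides the trivial state ``E0 = (0,0)`` (always a saddle) and the
predator-free state ``E1 = (1,0)`` (always a stable node — the Allee effect
is strong), interior equilibria are intersections of the two nontrivial
nullclines

    prey:     y = (1-x)(x+beta)
    predator: x = m*beta / (alpha*h(y) - m)     (requires alpha*h(y) > m)

The predator nullcline is strictly decreasing and convex in the first
quadrant, the prey nullcline is a downward parabola, so there are at most
two interior equilibria ``E1*`` (smaller x, never a saddle) and ``E2*``
(larger x, always a saddle).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
from scipy.optimize import brentq

from .allee import AlleeFunction
from .model import ModelParams, jacobian

__all__ = [
    "Equilibrium",
    "boundary_equilibria",
    "prey_nullcline_y",
    "predator_nullcline_x",
    "find_interior_equilibria",
    "classify_equilibrium",
]

TOL_EQ = 1e-10      # residual tolerance for equilibrium location
TOL_HYP = 1e-8      # |Re lambda| below this -> nonhyperbolic, no claim
_TANGENCY_TOL = 1e-8
_MERGE_TOL = 1e-7
_NGRID = 2048


@dataclass
class Equilibrium:
    """A fixed point with spectrum and labels.

    ``kind`` is one of ``E0``, ``E1`` (boundary), ``E1star`` (interior,
    non-saddle) or ``E2star`` (interior saddle).  ``topo_type`` is
    ``saddle`` / ``node`` / ``focus``; ``stability`` is ``stable`` /
    ``unstable`` / ``nonhyperbolic``.
    """

    x: float
    y: float
    kind: str
    eigenvalues: tuple
    trace: float
    det: float
    topo_type: str
    stability: str

    @property
    def location(self):
        return (self.x, self.y)


def prey_nullcline_y(x: float, beta: float) -> float:
    """Nontrivial prey nullcline ``y = (1-x)(x+beta)`` on ``0 <= x <= 1``.

    For ``0 < beta < 1`` its maximum ``(1+beta)^2/4`` sits at
    ``x_m = (1-beta)/2``; for ``beta >= 1`` the maximum on [0,1] is at x=0.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0,1]; got {x}")
    return (1.0 - x) * (x + beta)


def predator_nullcline_x(y: float, p: ModelParams, h: AlleeFunction) -> float:
    """Nontrivial predator nullcline ``x = m*beta/(alpha*h(y)-m)``.

    Returns ``nan`` where ``alpha*h(y) <= m`` (left of the vertical
    asymptote the nullcline does not exist).
    """
    if y <= 0:
        raise ValueError(f"y must be positive; got {y}")
    den = p.alpha * float(h.value(y)) - p.m
    if den <= 0:
        return float("nan")
    return p.m * p.beta / den


def _eig_labels(J: np.ndarray):
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    eig = np.linalg.eigvals(J)
    if det < 0:
        topo = "saddle"
    elif np.abs(eig.imag).max() > TOL_HYP:
        topo = "focus"
    else:
        topo = "node"
    remax = float(eig.real.max())
    if topo == "saddle":
        stab = "unstable"
    elif abs(remax) < TOL_HYP:
        stab = "nonhyperbolic"
    elif remax < 0:
        stab = "stable"
    else:
        stab = "unstable"
    return eig, tr, det, topo, stab


def boundary_equilibria(p: ModelParams, h: Optional[AlleeFunction] = None):
    """The two boundary equilibria ``E0=(0,0)`` and ``E1=(1,0)``.

    Independent of the Allee factor: ``h`` enters the Jacobian only through
    interior terms that vanish on the prey axis.  Eigenvalues are
    ``{1, -m}`` at E0 (saddle) and ``{-1, -m}`` at E1 (stable node).
    """
    m = p.m
    e0 = Equilibrium(0.0, 0.0, "E0", (1.0 + 0j, -m + 0j), 1.0 - m, -m,
                     "saddle", "unstable")
    e1 = Equilibrium(1.0, 0.0, "E1", (-1.0 + 0j, -m + 0j), -1.0 - m, m,
                     "node", "stable")
    return e0, e1


def _feasible_y_window(p: ModelParams, h: AlleeFunction):
    """Feasibility window of the interior-equilibrium reduction in y:
    ``(h^{-1}(m/alpha), (1+beta)^2/4]``; ``None`` when empty."""
    ymax = (1.0 + p.beta) ** 2 / 4.0
    c = p.m / p.alpha
    if c >= 1.0:
        return None
    ymin = h.inverse(c)
    if ymin >= ymax:
        return None
    return ymin, ymax


def _scalar_reduction(p: ModelParams, h: AlleeFunction):
    """G(y) whose roots on the feasibility window are the interior
    equilibria: substitute the predator nullcline into the prey one."""

    def G(y):
        den = p.alpha * float(h.value(y)) - p.m
        if den <= 0:
            return np.nan
        x = p.m * p.beta / den
        return (1.0 - x) * (x + p.beta) - y

    return G


def find_interior_equilibria(p: ModelParams, h: AlleeFunction,
                             classify: bool = True) -> List[Equilibrium]:
    """Locate the 0-2 interior equilibria, ordered by increasing x.

    The two nullcline equations are reduced to one scalar equation in y and
    bracketed on a log-spaced grid over the feasibility window; the proven
    monotone/convex nullcline geometry guarantees at most two sign changes.
    A near-tangency (scalar function touching zero without a sign change,
    magnitude < 1e-8) is reported as a single nonhyperbolic equilibrium.
    """
    win = _feasible_y_window(p, h)
    if win is None:
        return []
    ymin, ymax = win
    G = _scalar_reduction(p, h)
    lo = ymin * (1.0 + 1e-12) + 1e-300
    ys = np.geomspace(lo, ymax, _NGRID)
    den = p.alpha * np.asarray(h.value(ys), dtype=float) - p.m
    with np.errstate(divide="ignore", invalid="ignore"):
        xs = np.where(den > 0, p.m * p.beta / den, np.nan)
        vals = (1.0 - xs) * (xs + p.beta) - ys
    ok = np.isfinite(vals)
    roots: List[float] = []
    for i in range(len(ys) - 1):
        if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] < 0:
            roots.append(brentq(G, ys[i], ys[i + 1], xtol=1e-14, rtol=8.9e-16))
        elif ok[i] and vals[i] == 0.0:
            roots.append(float(ys[i]))
    tangency = False
    if not roots:
        j = int(np.nanargmin(np.abs(np.where(ok, vals, np.nan))))
        # near-tangency: refine the extremum of G between neighbouring
        # grid points, then apply the tolerance
        lo_j = ys[max(j - 1, 0)]
        hi_j = ys[min(j + 1, len(ys) - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda y: abs(G(y)),
                              bounds=(lo_j, hi_j), method="bounded",
                              options={"xatol": 1e-13})
        if np.isfinite(res.fun) and res.fun < _TANGENCY_TOL:
            roots = [float(res.x)]
            tangency = True
    # merge near-duplicates (a tangency resolved as two very close roots)
    merged: List[float] = []
    for r in sorted(roots):
        if merged and abs(r - merged[-1]) < _MERGE_TOL:
            merged[-1] = 0.5 * (merged[-1] + r)
            tangency = True
        else:
            merged.append(r)
    out = []
    for y in merged:
        x = p.m * p.beta / (p.alpha * float(h.value(y)) - p.m)
        if not 0.0 < x < 1.0:
            continue
        eq = Equilibrium(x, y, "E?", (0j, 0j), 0.0, 0.0, "?", "?")
        out.append(eq)
    out.sort(key=lambda e: e.x)
    for i, eq in enumerate(out):
        eq.kind = "E1star" if (i == 0 and not (len(out) == 1 and tangency)) else "E2star"
        if len(out) == 1 and tangency:
            eq.kind = "Estar_tangent"
    if classify:
        out = [classify_equilibrium(eq, p, h) for eq in out]
    return out


def classify_equilibrium(eq: Equilibrium, p: ModelParams,
                         h: AlleeFunction) -> Equilibrium:
    """Fill eigenvalues, trace/determinant and topological/stability labels
    from the Jacobian at the equilibrium."""
    J = jacobian((eq.x, eq.y), p, h)
    eig, tr, det, topo, stab = _eig_labels(J)
    return replace(eq, eigenvalues=tuple(eig), trace=tr, det=det,
                   topo_type=topo, stability=stab)


def slope_classification(eq: Equilibrium, p: ModelParams, h: AlleeFunction):
    """Independent classification of an interior equilibrium from the
    nullcline slopes (valid for ``0 < beta < 1``).

    The determinant sign follows from the ordering of the two nullcline
    slopes at the intersection; the trace sign from
    ``2(x_m - x) + alpha*x*h'(y)`` scaled by ``x/(beta+x)``.  Returns
    ``(is_saddle, trace_sign)``.
    """
    x, y = eq.x, eq.y
    b = p.beta
    slope_prey = 1.0 - b - 2.0 * x
    h1 = float(h.d1(y))
    hv = float(h.value(y))
    slope_pred = -b * hv / ((b + x) * x * h1)
    is_saddle = slope_pred > slope_prey
    tr = x / (b + x) * (1.0 - b - 2.0 * x) + p.alpha * x * y * h1 / (b + x)
    return is_saddle, np.sign(tr)
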