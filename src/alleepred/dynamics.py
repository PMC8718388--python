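"""Trajectories, limit cycles and dynamical regimes.

Cycle counting uses a Poincare first-return map on the vertical ray
``x = x1*, y > y1*`` through the non-saddle interior equilibrium: every
limit cycle encloses E1*, so it crosses the ray exactly once per period in
the leftward direction.  Roots of the displacement ``d(y0) = P(y0) - y0``
are cycles; their stability follows from the sign pattern of ``d`` on
either side (planar return maps are monotone, so the pattern is
unambiguous).  The outermost unstable cycle, when it bounds the collapse
basin, is found by bisecting the boundary between returning and
non-returning starts and checking that the displacement vanishes there
(otherwise the boundary is the saddle's stable manifold, not a cycle).

The regimes R1-R8 catalogue the phase portraits:

====  ===========  ======================================
name  E1*          limit cycles (inner to outer)
====  ===========  ======================================
R1    absent       none
R2    stable       none
R3    unstable     stable
R4    unstable     none
R5    stable       unstable
R6    unstable     stable, unstable
R7    stable       unstable, stable
R8    unstable     stable, unstable, stable
====  ===========  ======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .allee import AlleeFunction
from .bifurcation import BifurcationPoint, _full_params
from .equilibria import Equilibrium, find_interior_equilibria
from .model import ModelParams, jacobian, rhs

__all__ = [
    "Trajectory",
    "LimitCycle",
    "RegimeLabel",
    "integrate",
    "poincare_displacement",
    "find_limit_cycles",
    "classify_regime",
    "find_cycle_fold",
    "find_homoclinic",
    "DynamicsError",
]

#: integration tolerances (relative, absolute) for cycle-accurate work
TOL_CYCLE = (1e-10, 1e-12)
#: looser tolerances for classification sweeps
TOL_SWEEP = (1e-8, 1e-10)
#: predator densities below this are treated as collapsed (basin of E1)
COLLAPSE_Y = 1e-7
_RETURN_TMAX = 3000.0
_SWEEP_N = 120
_CAP_FACTOR = 8.0


class DynamicsError(RuntimeError):
    pass


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    events: List[Tuple[float, str]] = field(default_factory=list)

    @property
    def x(self):
        return self.states[:, 0]

    @property
    def y(self):
        return self.states[:, 1]


@dataclass
class LimitCycle:
    """A periodic orbit, keyed by its section crossing ``section_coord``
    (the y-value on the ray above E1*)."""

    section_coord: float
    period: float
    x_range: Tuple[float, float]
    stability: str
    return_slope: float


@dataclass
class RegimeLabel:
    region: str
    n_interior_eq: int
    n_cycles: int
    attractors: List[str]
    cycles: List[LimitCycle] = field(default_factory=list)
    equilibria: List[Equilibrium] = field(default_factory=list)


def integrate(p: ModelParams, h: AlleeFunction, s0, t_end: float,
              tol: Tuple[float, float] = TOL_SWEEP,
              dense: bool = False) -> Trajectory:
    """Integrate the model from ``s0`` for ``t_end`` time units (LSODA)."""
    x0, y0 = s0
    if x0 < 0 or y0 < 0:
        raise ValueError("initial state must be in the closed first quadrant")
    f = lambda t, s: rhs(s, p, h)
    sol = solve_ivp(f, (0.0, t_end), [x0, y0], method="LSODA",
                    rtol=tol[0], atol=tol[1], dense_output=dense)
    if not sol.success:
        raise DynamicsError(f"integration failed: {sol.message}; "
                            f"last state {sol.y[:, -1]}")
    return Trajectory(sol.t, sol.y.T)


def _first_return(p, h, x1, y0, tol=TOL_CYCLE, tmax=_RETURN_TMAX):
    """First same-direction return to the section x = x1 from (x1, y0).

    Returns (y_return, period, status); status is 'ok', 'collapse'
    (entered the predator-collapse basin of E1) or 'timeout'.
    """
    f = lambda t, s: rhs(s, p, h)

    def sec(t, s):
        return s[0] - x1

    sec.terminal = True
    sec.direction = -1

    def collapse(t, s):
        return s[1] - COLLAPSE_Y

    collapse.terminal = True
    collapse.direction = -1
    sol = solve_ivp(f, (0.0, tmax), [x1 - 1e-9, y0], method="LSODA",
                    events=[sec, collapse], rtol=tol[0], atol=tol[1],
                    first_step=1e-6)
    if sol.t_events[0].size:
        return float(sol.y_events[0][0][1]), float(sol.t_events[0][0]), "ok"
    if sol.t_events[1].size:
        return np.nan, np.nan, "collapse"
    return np.nan, np.nan, "timeout"


def poincare_displacement(p: ModelParams, h: AlleeFunction,
                          y_samples: Sequence[float],
                          tol=TOL_CYCLE):
    """Displacement ``d(y0) = first-return y - y0`` on the section through
    E1*, for each sample.  Non-returning samples carry ``nan`` and a
    status flag instead of a value."""
    eqs = find_interior_equilibria(p, h, classify=False)
    if not eqs:
        raise DynamicsError("no interior equilibrium: the section is undefined")
    x1, y1 = eqs[0].x, eqs[0].y
    out = []
    for y0 in y_samples:
        if y0 <= y1:
            raise ValueError(f"samples must lie above y1*={y1}")
        yr, per, st = _first_return(p, h, x1, y0, tol=tol)
        out.append((float(y0), yr - y0 if st == "ok" else np.nan, st))
    return out


def _sweep_displacement(p, h, x1, y1, tol, n=_SWEEP_N, cap=None):
    """Sweep d(y0) outward from E1*; refine the returning/non-returning
    boundary by bisection and sample densely on its inner side (outer
    cycles concentrate there).  Returns (samples, boundary) with samples
    sorted by y0."""
    cap = cap or _CAP_FACTOR * (1.0 + p.beta) ** 2 / 4.0
    cap = max(cap, 4.0 * y1)
    samples = []
    first_bad = None
    for y0 in np.geomspace(y1 * 1.0005, cap, n):
        yr, per, st = _first_return(p, h, x1, y0, tol=tol)
        if st == "ok":
            samples.append((y0, yr - y0))
        else:
            first_bad = y0
            break
    if first_bad is None:
        return samples, None
    if not samples:
        return samples, None
    a = samples[-1][0]
    b = first_bad
    for _ in range(50):
        mid = 0.5 * (a + b)
        yr, per, st = _first_return(p, h, x1, mid, tol=tol)
        if st == "ok":
            samples.append((mid, yr - mid))
            a = mid
        else:
            b = mid
        if b - a < 1e-12 * max(1.0, b):
            break
    samples.sort(key=lambda t: t[0])
    return samples, 0.5 * (a + b)


def find_limit_cycles(p: ModelParams, h: AlleeFunction,
                      tol=TOL_CYCLE, n_sweep: int = _SWEEP_N,
                      refine_tol: float = 1e-8) -> List[LimitCycle]:
    """All limit cycles, ordered inner to outer along the section.

    Cycles are isolated roots of the displacement map; each root is refined
    by bisection and classified from the displacement sign on both sides.
    Returns an empty list when no interior equilibrium exists (a planar
    cycle must enclose one).
    """
    eqs = find_interior_equilibria(p, h)
    eqs = [e for e in eqs if e.det > 0]
    if not eqs:
        return []
    e1 = eqs[0]
    x1, y1 = e1.x, e1.y
    samples, boundary = _sweep_displacement(p, h, x1, y1, tol, n=n_sweep)
    if not samples:
        return []

    def disp(y0):
        yr, per, st = _first_return(p, h, x1, y0, tol=tol)
        if st != "ok":
            raise DynamicsError(f"no return from y0={y0}")
        return yr - y0

    roots: List[float] = []
    for (ya, da), (yb, db) in zip(samples[:-1], samples[1:]):
        if da == 0.0:
            roots.append(ya)
        elif da * db < 0:
            roots.append(brentq(disp, ya, yb, xtol=refine_tol))
    out: List[LimitCycle] = []
    for r in roots:
        gap = min(1e-4 * r, 0.45 * min(
            [abs(r - rr) for rr in roots if rr != r] + [r - y1]))
        gap = max(gap, 1e-9)
        d_in, d_out = disp(r - gap), disp(r + gap)
        slope = (d_out - d_in) / (2 * gap) + 1.0
        stability = "stable" if (d_in > 0 and d_out < 0) else "unstable"
        yr, period, st = _first_return(p, h, x1, r, tol=tol)
        f = lambda t, s: rhs(s, p, h)
        sol = solve_ivp(f, (0.0, period), [x1, r], method="LSODA",
                        rtol=tol[0], atol=tol[1], max_step=period / 50.0)
        xr = (float(sol.y[0].min()), float(sol.y[0].max()))
        out.append(LimitCycle(float(r), float(period), xr, stability,
                              float(slope)))
    out.sort(key=lambda c: c.section_coord)
    return out


def classify_regime(p: ModelParams, h: AlleeFunction,
                    tol=TOL_CYCLE) -> RegimeLabel:
    """Classify the phase portrait into R1-R8 (see module docstring)."""
    eqs = find_interior_equilibria(p, h)
    nonsaddle = [e for e in eqs if e.det > 0]
    if not nonsaddle:
        return RegimeLabel("R1" if not eqs else "unclassified", len(eqs), 0,
                           ["E1"], equilibria=list(eqs))
    e1 = nonsaddle[0]
    cycles = find_limit_cycles(p, h, tol=tol)
    stable_eq = e1.stability == "stable"
    pattern = tuple(c.stability for c in cycles)
    key = (stable_eq, pattern)
    region = {
        (True, ()): "R2",
        (False, ("stable",)): "R3",
        (False, ()): "R4",
        (True, ("unstable",)): "R5",
        (False, ("stable", "unstable")): "R6",
        (True, ("unstable", "stable")): "R7",
        (False, ("stable", "unstable", "stable")): "R8",
    }.get(key, "unclassified")
    attractors = ["E1"]
    if stable_eq:
        attractors.append("E1star")
    attractors += [f"cycle@{c.section_coord:.4g}" for c in cycles
                   if c.stability == "stable"]
    return RegimeLabel(region, len(eqs), len(cycles), attractors,
                       cycles=cycles, equilibria=list(eqs))


def _cycle_count(params: Dict[str, float], allee_name: str, tol) -> int:
    from .allee import make_allee

    p = ModelParams(params["alpha"], params["beta"], params["m"])
    h = make_allee(allee_name, params["delta"])
    return len(find_limit_cycles(p, h, tol=tol))


def find_cycle_fold(params: Dict[str, float], free: str,
                    bracket: Tuple[float, float], allee_name: str = "monod",
                    xtol: float = 1e-6, tol=TOL_CYCLE) -> BifurcationPoint:
    """Fold of limit cycles: bisection on the free parameter where the
    cycle count changes by two (a stable/unstable pair collides)."""
    from .allee import make_allee

    lo, hi = bracket
    n_lo = _cycle_count(dict(params, **{free: lo}), allee_name, tol)
    n_hi = _cycle_count(dict(params, **{free: hi}), allee_name, tol)
    if abs(n_lo - n_hi) != 2:
        raise DynamicsError(
            f"cycle count changes by {abs(n_lo - n_hi)} (need 2) over the "
            f"bracket: {n_lo} at {lo}, {n_hi} at {hi}")
    a, b = lo, hi
    while abs(b - a) > xtol:
        mid = 0.5 * (a + b)
        n = _cycle_count(dict(params, **{free: mid}), allee_name, tol)
        if n == n_lo:
            a = mid
        else:
            b = mid
    val = 0.5 * (a + b)
    rich = dict(params, **{free: a if n_lo > n_hi else b})
    p = ModelParams(rich["alpha"], rich["beta"], rich["m"])
    h = make_allee(allee_name, rich["delta"])
    cycles = find_limit_cycles(p, h, tol=tol)
    pair = cycles[-2:] if len(cycles) >= 2 else cycles
    y_double = float(np.mean([c.section_coord for c in pair])) if pair else np.nan
    out_params = dict(params, **{free: val})
    return BifurcationPoint(
        "cycle_fold",
        {k: out_params[k] for k in ("alpha", "beta", "m", "delta")},
        np.nan, y_double,
        aux={"free": free, "count_low": min(n_lo, n_hi),
             "count_high": max(n_lo, n_hi)},
    )


def _saddle_manifold_crossing(p, h, e_saddle, e_focus, unstable: bool,
                              tol=TOL_CYCLE, tmax: float = 600.0):
    """Shoot the saddle's unstable (forward) or stable (backward) manifold
    to its first crossing of the section ray ``x = x1*, y > y1*`` through
    the focus; returns the y of the crossing.

    Near a homoclinic loop both manifold branches sweep over the focus and
    cross the ray; their y-offset is the signed miss distance.
    """
    J = jacobian((e_saddle.x, e_saddle.y), p, h)
    lam, vec = np.linalg.eig(J)
    lam = lam.real
    idx = int(np.argmax(lam)) if unstable else int(np.argmin(lam))
    v = vec[:, idx].real
    v = v / np.linalg.norm(v)
    sgn_t = 1.0 if unstable else -1.0
    f = lambda t, s: tuple(sgn_t * np.array(rhs(s, p, h)))

    def ray(t, s):
        return s[0] - e_focus.x

    ray.terminal = False

    def collapse(t, s):
        return s[1] - COLLAPSE_Y

    collapse.terminal = True
    collapse.direction = -1

    def far(t, s):
        return max(s[0] - 10.0, s[1] - 50.0)

    far.terminal = True

    eps = 1e-7 * max(1.0, abs(e_saddle.x))
    for sign in (+1.0, -1.0):
        z0 = np.array([e_saddle.x, e_saddle.y]) + sign * eps * v
        sol = solve_ivp(f, (0.0, tmax), z0, method="LSODA",
                        events=[ray, collapse, far],
                        rtol=tol[0], atol=tol[1], first_step=1e-8)
        for ye in sol.y_events[0]:
            if ye[1] > e_focus.y:
                return float(ye[1])
    return None


def homoclinic_miss(params: Dict[str, float], allee_name: str = "monod",
                    tol=TOL_CYCLE) -> float:
    """Signed miss distance between the saddle's unstable and stable
    manifolds on the transversal; zero at the homoclinic loop."""
    from .allee import make_allee

    p = ModelParams(params["alpha"], params["beta"], params["m"])
    h = make_allee(allee_name, params["delta"])
    eqs = find_interior_equilibria(p, h)
    saddles = [e for e in eqs if e.det < 0]
    foci = [e for e in eqs if e.det > 0]
    if not saddles or not foci:
        raise DynamicsError("need both a saddle and a non-saddle interior "
                            "equilibrium for homoclinic shooting")
    xs_u = _saddle_manifold_crossing(p, h, saddles[0], foci[0], True, tol)
    xs_s = _saddle_manifold_crossing(p, h, saddles[0], foci[0], False, tol)
    if xs_u is None or xs_s is None:
        raise DynamicsError("manifold branch did not reach the transversal")
    return xs_u - xs_s


def find_homoclinic(params: Dict[str, float], free: str,
                    bracket: Tuple[float, float], allee_name: str = "monod",
                    xtol: float = 1e-5, tol=TOL_CYCLE) -> BifurcationPoint:
    """Homoclinic loop: bisection on the sign change of the manifold miss
    distance over the free-parameter bracket."""
    lo, hi = bracket
    d_lo = homoclinic_miss(dict(params, **{free: lo}), allee_name, tol)
    d_hi = homoclinic_miss(dict(params, **{free: hi}), allee_name, tol)
    if d_lo * d_hi > 0:
        raise DynamicsError(
            f"miss distance does not change sign: {d_lo} at {lo}, "
            f"{d_hi} at {hi}")
    val = brentq(
        lambda v: homoclinic_miss(dict(params, **{free: v}), allee_name, tol),
        lo, hi, xtol=xtol)
    miss = homoclinic_miss(dict(params, **{free: val}), allee_name, tol)
    out_params = dict(params, **{free: val})
    return BifurcationPoint(
        "homoclinic",
        {k: out_params[k] for k in ("alpha", "beta", "m", "delta")},
        np.nan, np.nan,
        aux={"free": free, "miss": float(miss)},
    )
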