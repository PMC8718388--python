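"""Local bifurcations: saddle-node, Hopf, generalised Hopf, Bogdanov-Takens.

Saddle-node points are tangencies of the two nontrivial nullclines: the
equilibrium system plus the equal-slope condition
``f1_x f2_y - f1_y f2_x = 0`` (equivalently ``det J = 0``).  Hopf points are
zeros of ``trace J(E1*)`` with ``det J > 0``; at such a point the implicit
identity ``beta = 1 - 2 x1* + alpha y1* h'(y1*)`` holds.  A generalised
Hopf (Bautin) point is a Hopf point where the first Lyapunov coefficient
vanishes; a Bogdanov-Takens point has a double-zero eigenvalue
(``trace = det = 0``) and is classified by the sign of the product of the
two quadratic normal-form coefficients (BT+ / BT-), with the codimension-3
degeneracy BT0 where the second coefficient vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, root

from .allee import AlleeFunction, make_allee
from .equilibria import find_interior_equilibria
from .model import ModelParams, jacobian, rhs

__all__ = [
    "BifurcationPoint",
    "BifurcationCurve",
    "find_saddle_node",
    "find_hopf",
    "hopf_transversality",
    "first_lyapunov",
    "trace_curve",
    "find_BT",
    "find_GH_on_hopf",
    "BifurcationError",
]

TOL_GH = 1e-6
TOL_BT0 = 1e-6

_PARAM_NAMES = ("alpha", "beta", "m", "delta")


class BifurcationError(RuntimeError):
    pass


@dataclass
class BifurcationPoint:
    """A codimension-1/2/3 point: type, full parameter record, equilibrium
    location and diagnostics (transversality quantities, l1, BT normal-form
    coefficients)."""

    btype: str
    params: Dict[str, float]
    x: float
    y: float
    aux: Dict[str, float] = field(default_factory=dict)

    @property
    def location(self):
        return (self.x, self.y)


@dataclass
class BifurcationCurve:
    plane: Tuple[str, str]
    btype: str
    points: List[BifurcationPoint]
    truncated_reason: Optional[str] = None

    def values(self, key: str) -> np.ndarray:
        return np.array([pt.params[key] for pt in self.points])

    def aux_values(self, key: str) -> np.ndarray:
        return np.array([pt.aux.get(key, np.nan) for pt in self.points])


def _unpack(params: Dict[str, float]):
    p = ModelParams(params["alpha"], params["beta"], params["m"])
    h = make_allee(params.get("allee", "monod"), params["delta"]) \
        if "allee" in params else make_allee("monod", params["delta"])
    return p, h


def _make(params: Dict[str, float], allee_name: str):
    p = ModelParams(params["alpha"], params["beta"], params["m"])
    h = make_allee(allee_name, params["delta"])
    return p, h


def _full_params(p: ModelParams, h: AlleeFunction) -> Dict[str, float]:
    return {"alpha": p.alpha, "beta": p.beta, "m": p.m, "delta": h.delta}


def _defining_sn(u, params, free, allee_name):
    """(f1, f2, det J) at (x, y) with the free parameter substituted."""
    x, y, val = u
    pr = dict(params)
    pr[free] = val
    p, h = _make(pr, allee_name)
    b = p.beta
    hv, h1 = float(h.value(y)), float(h.d1(y))
    f1 = 1.0 - x - y / (x + b)
    f2 = p.alpha * x / (x + b) * hv - p.m
    J = jacobian((x, y), p, h)
    return [f1, f2, float(np.linalg.det(J))]


def _d2F_vv(p, h, x0, y0, v, eps=1e-5):
    """Directional second derivative D^2F(v, v) by central differences."""
    s0 = np.array([x0, y0])
    v = np.asarray(v, dtype=float)
    f = lambda s: np.array(rhs(s, p, h))
    return (f(s0 + eps * v) - 2.0 * f(s0) + f(s0 - eps * v)) / eps**2


def _dF_dparam(params, free, allee_name, x0, y0, eps=1e-7):
    out = []
    for sgn in (+1, -1):
        pr = dict(params)
        pr[free] = pr[free] + sgn * eps
        p, h = _make(pr, allee_name)
        out.append(np.array(rhs((x0, y0), p, h)))
    return (out[0] - out[1]) / (2.0 * eps)


def _count_interior(params, allee_name):
    p, h = _make(params, allee_name)
    return len(find_interior_equilibria(p, h, classify=False))


def find_saddle_node(params: Dict[str, float], free: str,
                     bracket: Tuple[float, float],
                     allee_name: str = "monod") -> BifurcationPoint:
    """Locate the nullcline tangency with respect to one free parameter.

    ``params`` holds alpha/beta/m/delta; ``free`` names the parameter
    varied over ``bracket``, across which the interior-equilibrium count
    must change (2 vs 0).  The 3-unknown system {prey nullcline, predator
    nullcline, det J = 0} is solved by Newton iteration seeded from a
    bisection on the equilibrium count.  ``aux`` records the two
    saddle-node transversality quantities ``w.F_param`` and
    ``w.D2F(v,v)`` (the second is negative for every admissible h).
    """
    lo, hi = bracket
    plo = dict(params, **{free: lo})
    phi = dict(params, **{free: hi})
    nlo, nhi = _count_interior(plo, allee_name), _count_interior(phi, allee_name)
    if (nlo >= 2) == (nhi >= 2):
        raise BifurcationError(
            f"equilibrium count does not change over the bracket "
            f"({nlo} at {lo}, {nhi} at {hi})")
    a, b = lo, hi
    for _ in range(50):
        mid = 0.5 * (a + b)
        n = _count_interior(dict(params, **{free: mid}), allee_name)
        if (n >= 2) == (nlo >= 2):
            a = mid
        else:
            b = mid
    val0 = 0.5 * (a + b)
    side = dict(params, **{free: a if nlo >= 2 else b})
    eqs = find_interior_equilibria(*_make(side, allee_name), classify=False)
    if len(eqs) == 1:
        x0, y0 = eqs[0].x, eqs[0].y
    else:
        x0 = 0.5 * (eqs[0].x + eqs[-1].x)
        y0 = 0.5 * (eqs[0].y + eqs[-1].y)
    sol = root(_defining_sn, [x0, y0, val0], args=(params, free, allee_name),
               method="hybr", tol=1e-13)
    if not sol.success:
        raise BifurcationError(f"saddle-node refinement failed: {sol.message}")
    x, y, val = sol.x
    pr = dict(params)
    pr[free] = val
    p, h = _make(pr, allee_name)
    J = jacobian((x, y), p, h)
    # right/left null vectors of J (zero eigenvalue)
    v = np.array([1.0, 1.0 - p.beta - 2.0 * x])
    w = np.array([p.alpha * y * float(h.d1(y)), 1.0])
    wF_param = float(w @ _dF_dparam(pr, free, allee_name, x, y))
    wD2F = float(w @ _d2F_vv(p, h, x, y, v))
    return BifurcationPoint(
        "SN", _full_params(p, h), float(x), float(y),
        aux={"det": float(np.linalg.det(J)), "trace": float(np.trace(J)),
             "w_F_param": wF_param, "w_D2F_vv": wD2F, "free": free},
    )


def _nonsaddle_interior(p, h):
    eqs = find_interior_equilibria(p, h)
    eqs = [e for e in eqs if e.det > 0]
    return eqs[0] if eqs else None


def find_hopf(params: Dict[str, float], free: str,
              bracket: Tuple[float, float],
              allee_name: str = "monod") -> BifurcationPoint:
    """Zero of ``trace J(E1*)`` in the free parameter, with ``det > 0``.

    Raises :class:`BifurcationError` (BT proximity) if the determinant is
    not positive at the root.  ``aux`` records trace, det and the residual
    of the implicit Hopf identity ``beta - (1 - 2x + alpha y h'(y))``.
    """

    def tr(val):
        pr = dict(params, **{free: val})
        p, h = _make(pr, allee_name)
        eq = _nonsaddle_interior(p, h)
        if eq is None:
            raise BifurcationError(
                f"no non-saddle interior equilibrium at {free}={val}")
        return eq.trace

    lo, hi = bracket
    t_lo, t_hi = tr(lo), tr(hi)
    if t_lo * t_hi > 0:
        raise BifurcationError("trace does not change sign over the bracket")
    val = brentq(tr, lo, hi, xtol=1e-13, rtol=8.9e-16)
    pr = dict(params, **{free: val})
    p, h = _make(pr, allee_name)
    eq = _nonsaddle_interior(p, h)
    if eq.det <= 0:
        raise BifurcationError("det <= 0 at the trace zero: Bogdanov-Takens "
                               "proximity, not a Hopf point")
    ident = p.beta - (1.0 - 2.0 * eq.x + p.alpha * eq.y * float(h.d1(eq.y)))
    return BifurcationPoint(
        "Hopf", _full_params(p, h), eq.x, eq.y,
        aux={"trace": eq.trace, "det": eq.det, "omega": np.sqrt(eq.det),
             "hopf_identity_residual": float(ident), "free": free},
    )


def hopf_transversality(bp: BifurcationPoint, allee_name: str = "monod",
                        step: float = 1e-5) -> float:
    """d(Re lambda)/d beta across the Hopf point, by Richardson-extrapolated
    central differences of trace/2 along the equilibrium branch in beta."""

    def re_lambda(beta):
        pr = dict(bp.params, beta=beta)
        p, h = _make(pr, allee_name)
        eq = _nonsaddle_interior(p, h)
        if eq is None:
            raise BifurcationError("equilibrium lost while differentiating")
        return 0.5 * eq.trace

    b0 = bp.params["beta"]
    d1 = (re_lambda(b0 + step) - re_lambda(b0 - step)) / (2 * step)
    d2 = (re_lambda(b0 + step / 2) - re_lambda(b0 - step / 2)) / step
    val = (4.0 * d2 - d1) / 3.0
    if abs(val) < 1e-10:
        import warnings

        warnings.warn("degenerate Hopf transversality (|d Re/d beta| < 1e-10)")
    return float(val)


def first_lyapunov(params: Dict[str, float], allee_name: str = "monod",
                   eq=None, fd_step: float = 1e-3) -> float:
    """First Lyapunov coefficient of the Hopf normal form at E1*.

    The field is translated to the equilibrium and rotated to the real
    normal frame ``u' = -w v + f(u,v), v' = w u + g(u,v)``; second/third
    partials of ``f`` and ``g`` are obtained by central differences and
    combined in the standard planar formula.  Only the sign is meaningful
    for the bifurcation scenario (negative = supercritical).
    """
    p, h = _make(params, allee_name)
    if eq is None:
        eq = _nonsaddle_interior(p, h)
        if eq is None:
            raise BifurcationError("no non-saddle interior equilibrium")
    x0, y0 = eq.x, eq.y
    J = jacobian((x0, y0), p, h)
    tr, det = float(np.trace(J)), float(np.linalg.det(J))
    if det <= 0 or abs(tr) > 1e-6:
        raise BifurcationError(f"not a Hopf point: trace={tr}, det={det}")
    om = np.sqrt(det)
    q = np.array([J[0, 1], 1j * om - J[0, 0]])
    T = np.column_stack([q.real, -q.imag])
    Ti = np.linalg.inv(T)
    center = np.array([x0, y0])

    def w_of(u, v):
        s = center + T @ np.array([u, v])
        return Ti @ np.array(rhs(s, p, h))

    eps = 1e-7
    A = np.column_stack([(w_of(eps, 0) - w_of(-eps, 0)) / (2 * eps),
                         (w_of(0, eps) - w_of(0, -eps)) / (2 * eps)])
    swap = A[1, 0] < 0  # orientation: standard frame has g_u = +omega

    def fnl(u, v):
        return w_of(u, v) - A @ np.array([u, v])

    hh = fd_step
    F0 = fnl(0.0, 0.0)

    def d2(fun, iu, iv):
        if (iu, iv) == (2, 0):
            return (fun(hh, 0) - 2 * fun(0, 0) + fun(-hh, 0)) / hh**2
        if (iu, iv) == (0, 2):
            return (fun(0, hh) - 2 * fun(0, 0) + fun(0, -hh)) / hh**2
        if (iu, iv) == (1, 1):
            return (fun(hh, hh) - fun(hh, -hh) - fun(-hh, hh) + fun(-hh, -hh)) / (4 * hh**2)
        raise ValueError

    def d3(fun, iu, iv):
        if (iu, iv) == (3, 0):
            return (fun(2 * hh, 0) - 2 * fun(hh, 0) + 2 * fun(-hh, 0) - fun(-2 * hh, 0)) / (2 * hh**3)
        if (iu, iv) == (0, 3):
            return (fun(0, 2 * hh) - 2 * fun(0, hh) + 2 * fun(0, -hh) - fun(0, -2 * hh)) / (2 * hh**3)
        if (iu, iv) == (2, 1):
            du2 = lambda v: (fun(hh, v) - 2 * fun(0, v) + fun(-hh, v)) / hh**2
            return (du2(hh) - du2(-hh)) / (2 * hh)
        if (iu, iv) == (1, 2):
            dv2 = lambda u: (fun(u, hh) - 2 * fun(u, 0) + fun(u, -hh)) / hh**2
            return (dv2(hh) - dv2(-hh)) / (2 * hh)
        raise ValueError

    f = lambda u, v: fnl(u, v)[0]
    g = lambda u, v: fnl(u, v)[1]
    fuu, fvv, fuv = d2(f, 2, 0), d2(f, 0, 2), d2(f, 1, 1)
    guu, gvv, guv = d2(g, 2, 0), d2(g, 0, 2), d2(g, 1, 1)
    fuuu, fuvv = d3(f, 3, 0), d3(f, 1, 2)
    guuv, gvvv = d3(g, 2, 1), d3(g, 0, 3)
    if swap:
        fuu, fvv, fuv, guu, gvv, guv = gvv, guu, guv, fvv, fuu, fuv
        fuuu, fuvv, guuv, gvvv = gvvv, guuv, fuvv, fuuu
    l1 = (fuuu + guuv + fuvv + gvvv) / 16.0 + (
        fuv * (fuu + fvv) - guv * (guu + gvv) - fuu * guu + fvv * gvv
    ) / (16.0 * om)
    return float(l1)


def _defining_hopf(u, params, free, allee_name):
    x, y, val = u
    pr = dict(params)
    pr[free] = val
    p, h = _make(pr, allee_name)
    b = p.beta
    hv = float(h.value(y))
    f1 = 1.0 - x - y / (x + b)
    f2 = p.alpha * x / (x + b) * hv - p.m
    J = jacobian((x, y), p, h)
    return [f1, f2, float(np.trace(J))]


def trace_curve(btype: str, plane: Tuple[str, str], fixed: Dict[str, float],
                allee_name: str = "monod",
                seed: Optional[BifurcationPoint] = None,
                step: float = 1e-3, step_max: float = 5e-2,
                step_min: float = 1e-6, max_points: int = 2000,
                bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                compute_l1: bool = False) -> BifurcationCurve:
    """Continue a saddle-node or Hopf curve in a two-parameter plane.

    Natural-parameter continuation with a secant predictor; near folds of
    the curve the stepped plane variable is swapped automatically (the
    defining system is re-solved for the other variable).  The curve is
    truncated at plane ``bounds``, on corrector failure, or after
    ``max_points`` points.
    """
    if btype not in ("sn", "hopf"):
        raise ValueError("btype must be 'sn' or 'hopf'")
    define = _defining_sn if btype == "sn" else _defining_hopf
    p1n, p2n = plane
    if seed is None:
        raise BifurcationError("a seed BifurcationPoint is required")
    bounds = bounds or {}

    def in_bounds(params):
        for k in (p1n, p2n):
            if not (np.isfinite(params[k]) and params[k] > 0):
                return False
            if k in bounds:
                lo, hi = bounds[k]
                if not lo <= params[k] <= hi:
                    return False
        return True

    def solve_for(params, free, guess):
        if params[p1n if free == p2n else p2n] <= 0:
            return None
        try:
            sol = root(define, guess, args=(params, free, allee_name),
                       method="hybr", tol=1e-13)
        except (ValueError, FloatingPointError):
            return None
        if not sol.success or sol.x[2] <= 0:
            return None
        return sol.x

    def mkpoint(x, y, params):
        p, h = _make(params, allee_name)
        J = jacobian((x, y), p, h)
        aux = {"trace": float(np.trace(J)), "det": float(np.linalg.det(J))}
        if compute_l1 and btype == "hopf" and aux["det"] > 1e-10:
            try:
                aux["l1"] = first_lyapunov(params, allee_name)
            except BifurcationError:
                aux["l1"] = np.nan
        return BifurcationPoint("SN" if btype == "sn" else "Hopf",
                                dict(params), float(x), float(y), aux)

    half_curves = []
    for direction in (+1, -1):
        pts: List[BifurcationPoint] = []
        reason = None
        params = dict(fixed)
        params[p1n] = seed.params[p1n]
        params[p2n] = seed.params[p2n]
        cur = np.array([seed.x, seed.y, params[p1n], params[p2n]])
        prev = None
        hstep = step * direction
        stepped, solved = p1n, p2n  # step p1, solve for p2
        n_fail = 0
        while len(pts) < max_points:
            tstep = np.zeros(4)
            if prev is not None:
                tstep = cur - prev
                nrm = abs(tstep[2] if stepped == p1n else tstep[3])
                if nrm > 0:
                    tstep = tstep / nrm
            target = dict(params)
            icur = 2 if stepped == p1n else 3
            target[stepped] = cur[icur] + hstep
            if target[stepped] <= 0 or (
                    stepped in bounds and not
                    bounds[stepped][0] <= target[stepped] <= bounds[stepped][1]):
                reason = "plane boundary"
                break
            guess = cur[:2] + tstep[:2] * abs(hstep)
            gval = cur[3 if stepped == p1n else 2] + (
                tstep[3 if stepped == p1n else 2]) * abs(hstep)
            sol = solve_for(target, solved, [guess[0], guess[1], gval])
            if sol is None:
                # try swapping the stepped variable (fold in the plane)
                stepped, solved = solved, stepped
                icur = 2 if stepped == p1n else 3
                target = dict(params)
                target[stepped] = cur[icur] + hstep * np.sign(
                    tstep[icur] if tstep[icur] != 0 else 1.0)
                gval = cur[3 if stepped == p1n else 2]
                sol = solve_for(target, solved, [cur[0], cur[1], gval])
            if sol is None:
                if abs(hstep) > step_min * 2:
                    hstep *= 0.3
                    n_fail += 1
                    if n_fail < 12:
                        continue
                reason = "corrector divergence"
                break
            x, y, vs = sol
            newp = dict(target)
            newp[solved] = vs
            # reject steps where the solved variable moves too fast
            # (steep segment: the plane curve folds w.r.t. the stepped one)
            dsol = abs(vs - params[solved])
            if dsol > step_max and abs(hstep) > step_min * 2:
                hstep *= 0.4
                n_fail += 1
                if n_fail < 12:
                    continue
            n_fail = 0
            if any(not (np.isfinite(newp[k]) and newp[k] > 0) for k in (p1n, p2n)):
                reason = "left the admissible plane"
                break
            if btype == "hopf":
                p_new, h_new = _make(newp, allee_name)
                if float(np.linalg.det(jacobian((x, y), p_new, h_new))) <= 0:
                    reason = "Bogdanov-Takens endpoint (det <= 0)"
                    break
            out_of_bounds = False
            for k in (p1n, p2n):
                if k in bounds:
                    lo, hi = bounds[k]
                    if not lo <= newp[k] <= hi:
                        out_of_bounds = True
            if out_of_bounds:
                reason = "plane boundary"
                break
            prev = cur
            cur = np.array([x, y, newp[p1n], newp[p2n]])
            params = newp
            pts.append(mkpoint(x, y, newp))
            if dsol > 2.0 * abs(hstep):
                # steep segment: step the faster-moving variable instead,
                # keeping the traversal direction from the secant
                stepped, solved = solved, stepped
                inew = 2 if stepped == p1n else 3
                hstep = np.sign(cur[inew] - prev[inew]) * abs(hstep)
            if abs(hstep) < step_max:
                hstep *= 1.3
                hstep = np.sign(hstep) * min(abs(hstep), step_max)
        half_curves.append((pts, reason))
    fwd, fwd_reason = half_curves[0]
    bwd, bwd_reason = half_curves[1]
    seed_pt = mkpoint(seed.x, seed.y,
                      dict(fixed, **{p1n: seed.params[p1n], p2n: seed.params[p2n]}))
    points = list(reversed(bwd)) + [seed_pt] + fwd
    return BifurcationCurve(plane, "SN" if btype == "sn" else "Hopf", points,
                            truncated_reason=fwd_reason or bwd_reason)


def _defining_bt(u, fixed, plane, allee_name):
    x, y, v1, v2 = u
    params = dict(fixed)
    params[plane[0]] = v1
    params[plane[1]] = v2
    p, h = _make(params, allee_name)
    b = p.beta
    hv = float(h.value(y))
    f1 = 1.0 - x - y / (x + b)
    f2 = p.alpha * x / (x + b) * hv - p.m
    J = jacobian((x, y), p, h)
    return [f1, f2, float(np.trace(J)), float(np.linalg.det(J))]


def find_BT(plane: Tuple[str, str], fixed: Dict[str, float],
            allee_name: str = "monod",
            guess: Sequence[float] = (0.7, 0.45, 0.15, 2.2)) -> BifurcationPoint:
    """Locate a Bogdanov-Takens point in a parameter plane and classify it.

    Solves {equilibrium, trace=0, det=0} for ``(x, y, plane params)``, then
    computes the two quadratic coefficients of the BT normal form from the
    generalised eigenvectors and the bilinear form of the field: label
    ``BTplus``/``BTminus`` by the sign of their product, ``BT0`` when the
    second (degeneracy) coefficient is below ``TOL_BT0``.
    """
    sol = root(_defining_bt, list(guess), args=(fixed, plane, allee_name),
               method="hybr", tol=1e-13)
    if not sol.success:
        raise BifurcationError(f"BT solve failed: {sol.message}")
    x, y, v1, v2 = sol.x
    params = dict(fixed)
    params[plane[0]], params[plane[1]] = v1, v2
    p, h = _make(params, allee_name)
    J = jacobian((x, y), p, h)
    q0 = np.array([-J[0, 1], J[0, 0]])
    if np.linalg.norm(q0) < 1e-12:
        q0 = np.array([J[1, 1], -J[1, 0]])
    q1 = np.linalg.lstsq(J, q0, rcond=None)[0]
    p1v = np.array([-J[1, 0], J[0, 0]])
    if np.linalg.norm(p1v) < 1e-12:
        p1v = np.array([J[1, 1], -J[0, 1]])
    p0v = np.linalg.lstsq(J.T, p1v, rcond=None)[0]
    p1v = p1v / (p1v @ q1)
    p0v = p0v / (p0v @ q0)
    q1 = q1 - (p0v @ q1) / (p0v @ q0) * q0

    eps = 1e-5
    s0 = np.array([x, y])
    F = lambda s: np.array(rhs(s, p, h))

    def B(u, v):
        return (F(s0 + eps * (u + v)) - F(s0 + eps * (u - v))
                - F(s0 - eps * (u - v)) + F(s0 - eps * (u + v))) / (4 * eps**2)

    a2 = 0.5 * float(p1v @ B(q0, q0))
    b2 = float(p0v @ B(q0, q0) + p1v @ B(q0, q1))
    if abs(b2) < TOL_BT0:
        label = "BT0"
    elif a2 * b2 > 0:
        label = "BTplus"
    else:
        label = "BTminus"
    return BifurcationPoint(
        label, _full_params(p, h), float(x), float(y),
        aux={"a2": a2, "b2": b2, "trace": float(np.trace(J)),
             "det": float(np.linalg.det(J))},
    )


def find_GH_on_hopf(curve: BifurcationCurve, allee_name: str = "monod",
                    tol: float = TOL_GH) -> List[BifurcationPoint]:
    """Sign changes of l1 along a Hopf curve, refined by bisection in the
    curve's first plane parameter."""
    p1n, p2n = curve.plane
    l1s = curve.aux_values("l1")
    out: List[BifurcationPoint] = []
    for i in range(len(curve.points) - 1):
        a, b = l1s[i], l1s[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)) or a * b >= 0:
            continue
        pa = curve.points[i]
        pb = curve.points[i + 1]

        def l1_at(t):
            params = {k: (1 - t) * pa.params[k] + t * pb.params[k]
                      for k in pa.params}
            guess = [(1 - t) * pa.x + t * pb.x, (1 - t) * pa.y + t * pb.y,
                     params[p2n]]
            sol = root(_defining_hopf, guess,
                       args=(params, p2n, allee_name), method="hybr", tol=1e-13)
            if not sol.success:
                raise BifurcationError("Hopf re-solve failed during GH refine")
            params[p2n] = sol.x[2]
            return first_lyapunov(params, allee_name), params, sol.x

        t_star = brentq(lambda t: l1_at(t)[0], 0.0, 1.0, xtol=1e-10)
        l1v, params, (x, y, _) = l1_at(t_star)
        if abs(l1v) <= max(tol, 1e-4 * max(abs(a), abs(b))):
            out.append(BifurcationPoint("GH", dict(params), float(x), float(y),
                                        aux={"l1": float(l1v)}))
    return out
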