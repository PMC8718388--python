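"""Structural sensitivity of the coexistence state to the Allee-factor shape.

The Allee factor is a partially specified model ingredient: only the
qualitative axioms (A1)-(A5) are biologically grounded, not any concrete
formula.  This module samples random admissible perturbations ``h1`` of a
base function ``h`` inside a relative band

    h(y) (1 - eps) <= h1(y) <= h(y) (1 + eps)

with the curvature bound ``-D < h1''(y) <= 0`` and ``h1' > 0``, and asks
how often the coexistence state E1* is stable across the sampled
neighbourhood.  The *degree of structural sensitivity*

    Delta = 4 p (1 - p),      p = fraction of stable outcomes,

is the probability that two independently drawn admissible functions
disagree on stability, normalised so that maximal uncertainty (p = 1/2)
gives Delta = 1 and unanimity gives 0.

Sampler: each draw mixes the three built-in parameterisations with
Dirichlet weights and jittered intensities, plus a random overall
amplitude within the band; draws violating the band, monotonicity or the
curvature bound on a log-spaced check grid are rejected.  The curvature
floor is enforced on the part of the grid where the base function itself
satisfies it (all built-in forms have ``h'' -> -O(1/delta^2)`` at the
origin, so a uniform floor near y=0 would exclude the base function too).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .allee import AlleeFunction, BUILTIN_ALLEE_NAMES, make_allee
from .equilibria import find_interior_equilibria
from .model import ModelParams

__all__ = [
    "PerturbationSpec",
    "SensitivityResult",
    "sample_perturbed_h",
    "degree_of_sensitivity",
    "sensitivity_scan",
    "SamplerError",
]

_MAX_TRIES = 1000


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class PerturbationSpec:
    """Perturbation neighbourhood of a base Allee function.

    ``epsilon``: relative band half-width (< 1); ``D``: curvature bound;
    ``n_samples``: number of admissible draws; ``seed``: RNG seed;
    ``check_grid``: grid on which the constraints are enforced (defaults
    to 512 log-spaced points on ``(0, 50*delta]``).
    """

    base: AlleeFunction
    epsilon: float
    D: float = 10.0
    n_samples: int = 200
    seed: int = 0
    check_grid: Optional[np.ndarray] = None
    delta_jitter: float = 0.12

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in [0,1); got {self.epsilon}")
        if self.D <= 0:
            raise ValueError(f"D must be positive; got {self.D}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.check_grid is None:
            object.__setattr__(
                self, "check_grid",
                np.geomspace(1e-4 * self.base.delta, 50.0 * self.base.delta,
                             512))

    def curvature_floor_mask(self) -> np.ndarray:
        """Grid points where the base itself respects ``h'' > -D`` (the
        floor is enforced there)."""
        g = self.check_grid
        return np.asarray(self.base.d2(g)) > -self.D * (1.0 - 1e-9)


def _perturbation(base: AlleeFunction, eps, c0, c1, c2, c3, d2v, d3v):
    """Candidate perturbation with analytic derivatives:

        h1 = h * (1 + eps*(c0 + c1*(2u - 1))) + eps*(c2*g2 + c3*g3)

    where ``u = y/(y + delta)`` and ``g2``/``g3`` are the differences
    between the Ivlev / tanh forms (with jittered intensities) and the
    base — a smooth tilt of the base plus form-mixing directions.
    ``c2``/``c3`` are pre-scaled by the caller so the additive part stays
    comparable to the band.
    """
    d = base.delta
    ivl = make_allee("ivlev", d2v)
    tnh = make_allee("tanh", d3v)

    def u(y):
        y = np.asarray(y, dtype=float)
        return y / (y + d)

    def u1(y):
        y = np.asarray(y, dtype=float)
        return d / (y + d) ** 2

    def u2(y):
        y = np.asarray(y, dtype=float)
        return -2.0 * d / (y + d) ** 3

    def eta(y):
        return eps * (c0 + c1 * (2.0 * u(y) - 1.0))

    def value(y):
        return (np.asarray(base.value(y)) * (1.0 + eta(y))
                + eps * (c2 * (np.asarray(ivl.value(y)) - np.asarray(base.value(y)))
                         + c3 * (np.asarray(tnh.value(y)) - np.asarray(base.value(y)))))

    def d1(y):
        return (np.asarray(base.d1(y)) * (1.0 + eta(y))
                + np.asarray(base.value(y)) * eps * 2.0 * c1 * u1(y)
                + eps * (c2 * (np.asarray(ivl.d1(y)) - np.asarray(base.d1(y)))
                         + c3 * (np.asarray(tnh.d1(y)) - np.asarray(base.d1(y)))))

    def d2f(y):
        return (np.asarray(base.d2(y)) * (1.0 + eta(y))
                + 2.0 * np.asarray(base.d1(y)) * eps * 2.0 * c1 * u1(y)
                + np.asarray(base.value(y)) * eps * 2.0 * c1 * u2(y)
                + eps * (c2 * (np.asarray(ivl.d2(y)) - np.asarray(base.d2(y)))
                         + c3 * (np.asarray(tnh.d2(y)) - np.asarray(base.d2(y)))))

    return value, d1, d2f


def sample_perturbed_h(spec: PerturbationSpec, k: int) -> AlleeFunction:
    """Draw the ``k``-th admissible perturbation; deterministic in
    ``(spec.seed, k)``.

    ``epsilon = 0`` returns the base function itself.  Raises
    :class:`SamplerError` when 1000 candidate draws are rejected (the
    neighbourhood is infeasible, e.g. ``D`` too small for the band).
    """
    base = spec.base
    if spec.epsilon == 0.0:
        return base
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, k]))
    g = spec.check_grid
    hb = np.asarray(base.value(g), dtype=float)
    floor_mask = spec.curvature_floor_mask()
    lo, hi = hb * (1.0 - spec.epsilon), hb * (1.0 + spec.epsilon)
    for _ in range(_MAX_TRIES):
        # tilt coefficients with |c0| + |c1| <= 1
        c0 = rng.uniform(-1.0, 1.0)
        c1 = rng.uniform(-1.0, 1.0) * (1.0 - abs(c0))
        # form-mixing directions, pre-scaled to the band
        d2v = base.delta * float(np.exp(rng.normal(0.0, spec.delta_jitter)))
        d3v = base.delta * float(np.exp(rng.normal(0.0, spec.delta_jitter)))
        ivl = make_allee("ivlev", d2v)
        tnh = make_allee("tanh", d3v)
        s2 = float(np.max(np.abs((np.asarray(ivl.value(g)) - hb) / hb)))
        s3 = float(np.max(np.abs((np.asarray(tnh.value(g)) - hb) / hb)))
        c2 = rng.uniform(-1.0, 1.0) * 0.5 / max(s2, 1e-12)
        c3 = rng.uniform(-1.0, 1.0) * 0.5 / max(s3, 1e-12)
        value, d1, d2f = _perturbation(base, spec.epsilon, c0, c1, c2, c3,
                                       d2v, d3v)
        v = np.asarray(value(g))
        if np.any(v < lo) or np.any(v > hi):
            continue
        if np.any(np.asarray(d1(g)) <= 0.0):
            continue
        curv = np.asarray(d2f(g))
        if np.any(curv > 1e-12):
            continue
        if np.any(curv[floor_mask] <= -spec.D):
            continue
        return AlleeFunction("custom", base.delta, value, d1, d2f)
    raise SamplerError(
        f"no admissible perturbation found in {_MAX_TRIES} tries "
        f"(epsilon={spec.epsilon}, D={spec.D})")


@dataclass
class SensitivityResult:
    p_stable: float
    delta_degree: float
    n_valid: int
    records: List[dict] = field(default_factory=list)


def degree_of_sensitivity(p: ModelParams, spec: PerturbationSpec,
                          lost_state: str = "unstable") -> SensitivityResult:
    """Stability of E1* across the perturbation neighbourhood.

    For each sample the interior equilibria are recomputed with the
    perturbed factor and the non-saddle one is classified.  Samples for
    which the coexistence state disappears are counted as unstable
    outcomes by default (``lost_state='unstable'``: destabilisation in the
    extinction sense) or excluded (``lost_state='exclude'``).
    """
    if lost_state not in ("unstable", "exclude"):
        raise ValueError("lost_state must be 'unstable' or 'exclude'")
    base_eqs = [e for e in find_interior_equilibria(p, spec.base) if e.det > 0]
    if not base_eqs:
        raise ValueError("base model has no coexistence state E1*")
    records = []
    n_stable = 0
    n_valid = 0
    for k in range(spec.n_samples):
        h1 = sample_perturbed_h(spec, k)
        eqs = [e for e in find_interior_equilibria(p, h1) if e.det > 0]
        if not eqs:
            rec = {"k": k, "outcome": "lost", "x": np.nan, "y": np.nan}
            if lost_state == "unstable":
                n_valid += 1
        else:
            e1 = eqs[0]
            stable = e1.stability == "stable"
            rec = {"k": k, "outcome": "stable" if stable else "unstable",
                   "x": e1.x, "y": e1.y}
            n_valid += 1
            n_stable += int(stable)
        records.append(rec)
    if n_valid < 10:
        raise ValueError(f"only {n_valid} valid samples (need >= 10)")
    p_stable = n_stable / n_valid
    return SensitivityResult(p_stable, 4.0 * p_stable * (1.0 - p_stable),
                             n_valid, records)


def sensitivity_scan(p_template: ModelParams, spec: PerturbationSpec,
                     beta_grid, lost_state: str = "unstable") -> pd.DataFrame:
    """``degree_of_sensitivity`` at each beta with common random numbers
    (the perturbation draws depend only on (seed, k), not on beta)."""
    rows = []
    for beta in np.asarray(beta_grid, dtype=float):
        p = ModelParams(p_template.alpha, beta, p_template.m)
        try:
            res = degree_of_sensitivity(p, spec, lost_state=lost_state)
            rows.append({"beta": beta, "p_stable": res.p_stable,
                         "delta_degree": res.delta_degree,
                         "n_valid": res.n_valid})
        except ValueError:
            rows.append({"beta": beta, "p_stable": np.nan,
                         "delta_degree": np.nan, "n_valid": 0})
    return pd.DataFrame(rows)
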