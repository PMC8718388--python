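"""Trajectories, return maps, limit cycles, regimes, global bifurcations."""

import numpy as np
import pytest

from alleepred import (ModelParams, classify_regime, find_cycle_fold,
                       find_homoclinic, find_interior_equilibria,
                       find_limit_cycles, get_fixture, integrate, make_allee,
                       poincare_displacement)
from alleepred.dynamics import DynamicsError, homoclinic_miss, \
    _first_return, _sweep_displacement


def fixture_setup(fid):
    f = get_fixture(fid)
    return f.model_params(), f.allee_function()


class TestIntegrate:
    def test_equilibrium_is_stationary(self):
        p, h = fixture_setup("fig7b")
        eq = find_interior_equilibria(p, h)[0]
        traj = integrate(p, h, (eq.x, eq.y), 100.0, tol=(1e-10, 1e-12))
        assert np.max(np.abs(traj.states - [eq.x, eq.y])) < 1e-6

    def test_r1_converges_to_prey_only_state(self):
        p, h = fixture_setup("fig7a")
        for s0 in [(0.5, 0.5), (0.2, 1.0), (0.9, 0.1)]:
            traj = integrate(p, h, s0, 500.0)
            assert traj.states[-1] == pytest.approx([1.0, 0.0], abs=1e-5)

    def test_first_quadrant_forward_invariant(self, rng):
        p, h = fixture_setup("fig7d")
        for _ in range(20):
            s0 = (float(rng.uniform(0.01, 1.5)), float(rng.uniform(0.01, 2.0)))
            traj = integrate(p, h, s0, 200.0)
            assert traj.states.min() > -1e-9

    def test_rejects_negative_start(self):
        p, h = fixture_setup("fig7a")
        with pytest.raises(ValueError):
            integrate(p, h, (-0.1, 0.5), 10.0)


class TestReturnMap:
    def test_displacement_vanishes_on_cycle(self):
        p, h = fixture_setup("fig7c")
        cyc = find_limit_cycles(p, h)[0]
        (y0, d, st), = poincare_displacement(p, h, [cyc.section_coord])
        assert st == "ok"
        assert abs(d) < 1e-6

    def test_sign_change_straddles_cycle(self):
        p, h = fixture_setup("fig7c")
        cyc = find_limit_cycles(p, h)[0]
        res = poincare_displacement(
            p, h, [cyc.section_coord * 0.97, cyc.section_coord * 1.03])
        assert res[0][1] > 0 > res[1][1]

    def test_slope_matches_two_point_estimate(self):
        p, h = fixture_setup("fig7c")
        cyc = find_limit_cycles(p, h)[0]
        r = cyc.section_coord
        res = poincare_displacement(p, h, [r - 1e-4, r + 1e-4])
        slope = (res[1][1] - res[0][1]) / 2e-4 + 1.0
        assert slope == pytest.approx(cyc.return_slope, abs=5e-2)
        assert -1 < slope < 1  # stable cycle

    def test_samples_below_section_rejected(self):
        p, h = fixture_setup("fig7c")
        with pytest.raises(ValueError):
            poincare_displacement(p, h, [0.01])


class TestLimitCycles:
    def test_bistable_cycle_pair(self):
        """Stable focus surrounded by an unstable then a stable cycle."""
        p, h = fixture_setup("fig7g")
        cyc = find_limit_cycles(p, h)
        assert [c.stability for c in cyc] == ["unstable", "stable"]
        assert cyc[0].section_coord == pytest.approx(1.5356, abs=2e-3)
        assert cyc[1].section_coord == pytest.approx(2.6840, abs=2e-3)

    def test_three_nested_cycles(self):
        p, h = fixture_setup("fig7h")
        cyc = find_limit_cycles(p, h)
        assert [c.stability for c in cyc] == ["stable", "unstable", "stable"]

    def test_cycles_strictly_nested(self):
        p, h = fixture_setup("fig7h")
        cyc = find_limit_cycles(p, h)
        for inner, outer in zip(cyc[:-1], cyc[1:]):
            assert inner.section_coord < outer.section_coord
            assert inner.x_range[0] > outer.x_range[0]
            assert inner.x_range[1] < outer.x_range[1]

    def test_stabilities_alternate(self):
        for fid in ("fig7c", "fig7g", "fig7h"):
            p, h = fixture_setup(fid)
            eq = [e for e in find_interior_equilibria(p, h) if e.det > 0][0]
            cyc = find_limit_cycles(p, h)
            want = "unstable" if eq.stability == "stable" else "stable"
            for c in cyc:
                assert c.stability == want
                want = "stable" if want == "unstable" else "unstable"

    def test_no_interior_equilibrium_no_cycles(self):
        p, h = fixture_setup("fig7a")
        assert find_limit_cycles(p, h) == []

    def test_single_unstable_cycle_regime(self):
        # inside the thin strip between the Hopf and homoclinic curves
        p = ModelParams(7.1, 0.8, 2.30)
        h = make_allee("monod", 0.085)
        cyc = find_limit_cycles(p, h)
        assert [c.stability for c in cyc] == ["unstable"]


class TestRegimes:
    # computed regimes; fig7e/fig7f sit marginally outside their claimed
    # regions (see the fixtures module) and classify as R2/R4
    @pytest.mark.parametrize("fid,region", [
        ("fig7a", "R1"), ("fig7b", "R2"), ("fig7c", "R3"), ("fig7d", "R4"),
        ("fig7e", "R2"), ("fig7f", "R4"), ("fig7g", "R7"), ("fig7h", "R8"),
    ])
    def test_catalogue(self, fid, region):
        p, h = fixture_setup(fid)
        assert classify_regime(p, h).region == region

    def test_true_r5_and_r6_points(self):
        assert classify_regime(ModelParams(7.1, 0.8, 2.30),
                               make_allee("monod", 0.085)).region == "R5"
        assert classify_regime(ModelParams(7.1, 0.8, 1.48),
                               make_allee("monod", 0.03)).region == "R6"

    def test_rosenzweig_macarthur_limit(self):
        """For delta -> 0 the classification reduces to the classical
        criterion: the coexistence state is stable iff the predator
        nullcline x* = m*beta/(alpha-m) sits right of the prey-nullcline
        maximum x_m = (1-beta)/2."""
        h = make_allee("monod", 1e-6)
        for m, expect in [(1.0, "R2"), (0.6, "R3")]:
            p = ModelParams(7.1, 0.8, m)
            x_star = m * p.beta / (p.alpha - m)
            x_m = (1 - p.beta) / 2
            lab = classify_regime(p, h)
            if x_star > x_m:
                assert expect == "R2" and lab.region == "R2"
            else:
                assert expect == "R3" and lab.region == "R3"


class TestGlobalBifurcations:
    def test_cycle_fold_location(self):
        """The stable/unstable pair of the two-cycle regime collides at
        delta = 0.0297 on the m=1.456 line."""
        bp = find_cycle_fold({"alpha": 7.1, "beta": 0.8, "m": 1.456,
                              "delta": 0.03}, "delta", (0.028, 0.031))
        assert bp.params["delta"] == pytest.approx(0.02969, abs=2e-4)
        assert (bp.aux["count_low"], bp.aux["count_high"]) == (0, 2)

    def test_cycle_fold_requires_count_change_of_two(self):
        with pytest.raises(DynamicsError, match="need 2"):
            find_cycle_fold({"alpha": 7.1, "beta": 0.8, "m": 1.456,
                             "delta": 0.03}, "delta", (0.026, 0.032))

    def test_homoclinic_location_and_sign_change(self):
        """The unstable cycle of the R5 strip dies in a saddle loop at
        m = 2.3236 (delta=0.085 line)."""
        bp = find_homoclinic({"alpha": 7.1, "beta": 0.8, "m": 2.3,
                              "delta": 0.085}, "m", (2.28, 2.40))
        assert bp.params["m"] == pytest.approx(2.3236, abs=1e-3)
        assert abs(bp.aux["miss"]) < 1e-4

    def test_miss_distance_matches_return_boundary_gap(self):
        """Dual route: the manifold miss distance equals the displacement
        measured at the returning/non-returning boundary of the return
        map (both measure the gap between the saddle's manifolds)."""
        params = {"alpha": 7.1, "beta": 0.8, "m": 2.4, "delta": 0.085}
        miss = homoclinic_miss(params)
        p = ModelParams(7.1, 0.8, 2.4)
        h = make_allee("monod", 0.085)
        eq = find_interior_equilibria(p, h, classify=False)[0]
        samples, boundary = _sweep_displacement(p, h, eq.x, eq.y,
                                                (1e-10, 1e-12))
        d_at_boundary = samples[-1][1]
        assert miss == pytest.approx(d_at_boundary, abs=1e-3)

    def test_cycle_grows_toward_homoclinic(self):
        """Approaching the saddle loop, the unstable cycle's period grows
        and its section coordinate approaches the basin boundary."""
        periods = []
        for m in (2.29, 2.31):
            p = ModelParams(7.1, 0.8, m)
            h = make_allee("monod", 0.085)
            cyc = find_limit_cycles(p, h)[0]
            periods.append(cyc.period)
        assert periods[1] > periods[0]
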