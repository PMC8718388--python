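"""Saddle-node, Hopf, first Lyapunov coefficient, BT and GH machinery."""

import numpy as np
import pytest

from alleepred import (ModelParams, find_BT, find_GH_on_hopf, find_hopf,
                       find_interior_equilibria, find_limit_cycles,
                       find_saddle_node, first_lyapunov, hopf_transversality,
                       make_allee, trace_curve)
from alleepred.bifurcation import BifurcationError

FIG2 = {"alpha": 1.8, "beta": 0.8, "m": 0.5, "delta": 0.25}
FIG8 = {"alpha": 7.1, "beta": 0.9, "m": 1.8, "delta": 0.12}


def sweep_sn_oracle(params, free, lo, hi, allee_name="monod", tol=1e-7):
    """Independent saddle-node locator: plain bisection on the interior
    equilibrium count."""
    def count(v):
        pr = dict(params, **{free: v})
        p = ModelParams(pr["alpha"], pr["beta"], pr["m"])
        return len(find_interior_equilibria(p, make_allee(allee_name,
                                                          pr["delta"]),
                                            classify=False))
    n_lo = count(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if count(mid) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSaddleNode:
    def test_tangency_delta(self):
        """The nullclines of the fig2 slice become tangent at
        delta = 0.311538 (frozen from the independent sweep oracle)."""
        bp = find_saddle_node(FIG2, "delta", (0.1, 0.4))
        assert bp.params["delta"] == pytest.approx(0.3115384615, abs=1e-8)
        assert abs(bp.aux["det"]) < 1e-8

    def test_agrees_with_sweep_oracle(self):
        bp = find_saddle_node(FIG2, "delta", (0.1, 0.4))
        assert bp.params["delta"] == pytest.approx(
            sweep_sn_oracle(FIG2, "delta", 0.1, 0.4), abs=1e-6)

    def test_transversality_signs(self):
        # d/dm direction: w.F_m = -y_bar < 0; w.D2F(v,v) < 0 for any
        # admissible h (guaranteed by h'' <= 0)
        bp = find_saddle_node(FIG2, "m", (0.3, 0.8))
        assert bp.aux["w_F_param"] == pytest.approx(-bp.y, rel=1e-6)
        assert bp.aux["w_D2F_vv"] < 0

    @pytest.mark.parametrize("name", ["monod", "ivlev", "tanh"])
    def test_second_transversality_negative_all_forms(self, name):
        bracket = {"monod": (0.1, 0.5), "ivlev": (0.3, 0.8),
                   "tanh": (0.5, 1.1)}[name]
        bp = find_saddle_node(FIG2, "delta", bracket, allee_name=name)
        assert bp.aux["w_D2F_vv"] < 0
        assert abs(bp.aux["det"]) < 1e-8

    def test_no_count_change_raises(self):
        with pytest.raises(BifurcationError, match="count"):
            find_saddle_node(FIG2, "delta", (0.05, 0.1))


class TestHopf:
    def test_threshold_beta(self):
        """Trace of J(E1*) vanishes at beta = 0.981890 for the structural-
        sensitivity base case (frozen; dual-checked via the implicit
        identity below)."""
        bp = find_hopf(FIG8, "beta", (0.8, 1.1))
        assert bp.params["beta"] == pytest.approx(0.9818902654, abs=1e-8)

    def test_purely_imaginary_eigenvalues(self):
        bp = find_hopf(FIG8, "beta", (0.8, 1.1))
        assert abs(bp.aux["trace"]) < 1e-10
        assert bp.aux["det"] > 0
        assert bp.aux["omega"] > 0.1

    def test_implicit_identity(self):
        # beta_H = 1 - 2 x1* + alpha y1* h'(y1*) regardless of freed param
        bp_beta = find_hopf(FIG8, "beta", (0.8, 1.1))
        assert abs(bp_beta.aux["hopf_identity_residual"]) < 1e-8
        bp_m = find_hopf({"alpha": 7.1, "beta": 0.8, "m": 2.0, "delta": 0.05},
                         "m", (1.0, 2.5))
        assert abs(bp_m.aux["hopf_identity_residual"]) < 1e-8

    def test_stability_flips_across_threshold(self):
        bp = find_hopf(FIG8, "beta", (0.8, 1.1))
        bH = bp.params["beta"]
        labels = {}
        for db in (-1e-3, 1e-3):
            p = ModelParams(7.1, bH + db, 1.8)
            eqs = find_interior_equilibria(p, make_allee("monod", 0.12))
            labels[db] = [e for e in eqs if e.det > 0][0].stability
        assert {labels[-1e-3], labels[1e-3]} == {"stable", "unstable"}
        # beta below threshold destabilises (eutrophication direction)
        assert labels[-1e-3] == "unstable"

    def test_transversality_nonzero_and_consistent(self):
        bp = find_hopf(FIG8, "beta", (0.8, 1.1))
        d = hopf_transversality(bp)
        assert abs(d) > 1e-4
        # Re(lambda) decreases with beta: stable above, unstable below
        assert d < 0

    def test_transversality_richardson_stable(self):
        bp = find_hopf(FIG8, "beta", (0.8, 1.1))
        d1 = hopf_transversality(bp, step=1e-4)
        d2 = hopf_transversality(bp, step=5e-5)
        assert d1 == pytest.approx(d2, rel=1e-5)


class TestFirstLyapunov:
    def test_supercritical_sign_confirmed_by_simulation(self):
        """On the alpha=6.0 slice the Hopf is supercritical: l1 < 0, and a
        small stable cycle exists only on the unstable side of the
        threshold."""
        params = {"alpha": 6.0, "beta": 0.8, "m": 1.0, "delta": 0.02}
        bp = find_hopf(params, "m", (0.6, 1.4))
        l1 = first_lyapunov(bp.params)
        assert l1 < 0
        m_h = bp.params["m"]
        h = make_allee("monod", 0.02)
        # trace decreases with m: unstable side is m < m_h
        cyc_unstable_side = find_limit_cycles(
            ModelParams(6.0, 0.8, m_h - 0.01), h)
        cyc_stable_side = find_limit_cycles(
            ModelParams(6.0, 0.8, m_h + 0.01), h)
        assert [c.stability for c in cyc_unstable_side] == ["stable"]
        assert cyc_unstable_side[0].x_range[1] - cyc_unstable_side[0].x_range[0] < 0.4
        assert cyc_stable_side == []

    def test_subcritical_at_sensitivity_base_case(self):
        bp = find_hopf(FIG8, "beta", (0.8, 1.1))
        assert first_lyapunov(bp.params) > 0

    def test_requires_hopf_conditions(self):
        with pytest.raises(BifurcationError, match="not a Hopf"):
            first_lyapunov({"alpha": 7.1, "beta": 0.8, "m": 2.0,
                            "delta": 0.2})


class TestBogdanovTakens:
    @pytest.mark.parametrize("alpha,guess,label", [
        (7.1, (0.7, 0.45, 0.12, 2.5), "BTplus"),
        (6.6, (0.7, 0.45, 0.14, 2.3), "BTminus"),
        (6.0, (0.7, 0.45, 0.17, 2.0), "BTminus"),
    ])
    def test_sign_classification(self, alpha, guess, label):
        """The BT normal-form sign decides the route between the locally
        stable and globally unstable coexistence regimes: positive on the
        alpha=7.1 slice (homoclinic route via R5), negative at 6.6/6.0
        (supercritical route via R3)."""
        bt = find_BT(("delta", "m"), {"alpha": alpha, "beta": 0.8},
                     guess=guess)
        assert bt.btype == label
        assert abs(bt.aux["trace"]) < 1e-8
        assert abs(bt.aux["det"]) < 1e-8

    def test_lies_on_sn_and_hopf_curves(self):
        bt = find_BT(("delta", "m"), {"alpha": 7.1, "beta": 0.8},
                     guess=(0.7, 0.45, 0.12, 2.5))
        d_bt, m_bt = bt.params["delta"], bt.params["m"]
        # the saddle-node curve passes through the BT point
        sn = find_saddle_node({"alpha": 7.1, "beta": 0.8, "m": 2.0,
                               "delta": d_bt}, "m", (m_bt - 0.4, m_bt + 0.4))
        assert sn.params["m"] == pytest.approx(m_bt, abs=1e-8)
        # the Hopf curve terminates at it: points exist arbitrarily close
        hp = find_hopf({"alpha": 7.1, "beta": 0.8, "m": 2.0,
                        "delta": d_bt - 1e-3}, "m", (1.0, m_bt))
        assert hp.params["m"] == pytest.approx(m_bt, abs=0.05)


class TestContinuationAndGH:
    @pytest.fixture(scope="class")
    def hopf_curve_66(self):
        seed = find_hopf({"alpha": 6.6, "beta": 0.8, "m": 1.6,
                          "delta": 0.05}, "m", (1.0, 2.2))
        return trace_curve("hopf", ("delta", "m"),
                           {"alpha": 6.6, "beta": 0.8}, seed=seed,
                           compute_l1=True,
                           bounds={"delta": (0.004, 0.2), "m": (0.2, 3.2)},
                           step=2e-3, step_max=4e-3, max_points=80)

    def test_curve_points_satisfy_defining_system(self, hopf_curve_66):
        assert len(hopf_curve_66.points) > 20
        for pt in hopf_curve_66.points[::10]:
            assert abs(pt.aux["trace"]) < 1e-9
            assert pt.aux["det"] > 0

    def test_cold_start_reverification(self, hopf_curve_66):
        """Every 10th curve point re-solved from scratch lands on the same
        parameter value."""
        for pt in hopf_curve_66.points[2:-2:10]:
            re = find_hopf(dict(pt.params), "m",
                           (pt.params["m"] - 0.05, pt.params["m"] + 0.05))
            assert re.params["m"] == pytest.approx(pt.params["m"], abs=1e-9)

    def test_consecutive_gaps_bounded(self, hopf_curve_66):
        d = hopf_curve_66.values("delta")
        m = hopf_curve_66.values("m")
        gaps = np.hypot(np.diff(d), np.diff(m))
        assert np.max(gaps) < 5e-2

    def test_gh_present_on_66_slice(self, hopf_curve_66):
        gh = find_GH_on_hopf(hopf_curve_66)
        assert len(gh) >= 1
        for g in gh:
            assert abs(g.aux["l1"]) < 1e-6

    def test_gh_absent_on_60_slice(self):
        seed = find_hopf({"alpha": 6.0, "beta": 0.8, "m": 1.4,
                          "delta": 0.05}, "m", (1.0, 2.0))
        curve = trace_curve("hopf", ("delta", "m"),
                            {"alpha": 6.0, "beta": 0.8}, seed=seed,
                            compute_l1=True,
                            bounds={"delta": (0.004, 0.2), "m": (0.2, 3.2)},
                            step=2e-3, step_max=4e-3, max_points=80)
        assert find_GH_on_hopf(curve) == []

    def test_no_triple_equilibrium_along_sn_curve(self):
        """Cusp impossibility: along the saddle-node curve the equilibrium
        count never exceeds 2 (checked just inside the fold)."""
        seed = find_saddle_node({"alpha": 7.1, "beta": 0.8, "m": 2.0,
                                 "delta": 0.2}, "delta", (0.1, 0.4))
        curve = trace_curve("sn", ("delta", "m"), {"alpha": 7.1, "beta": 0.8},
                            seed=seed,
                            bounds={"delta": (0.02, 0.45), "m": (0.5, 3.2)},
                            step=5e-3, step_max=2e-2, max_points=60)
        h_name = "monod"
        for pt in curve.points[::5]:
            p = ModelParams(7.1, 0.8, pt.params["m"])
            h = make_allee(h_name, pt.params["delta"] * 0.98)
            assert len(find_interior_equilibria(p, h, classify=False)) <= 2
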