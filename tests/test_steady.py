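"""Root finding, stability, regime classification, sweeps and scans."""

import dataclasses

import numpy as np
import pytest

import tcswitch as t
from helpers import dense_grid_roots, stability_by_integration
from tcswitch.models import integrate
from tcswitch.params import ReducedParams
from tcswitch.steady import SteadyStateSet, clamp_for_display


class TestFindSteadyStates:
    def test_t281r_defaults_are_bistable(self, t281r):
        ss = t.find_steady_states("reduced", t281r)
        assert len(ss) == 3
        assert ss.stabilities == ["stable", "unstable", "stable"]
        assert np.all(np.diff(ss.pstars) > 0)

    def test_wild_type_single_state_across_kinase_sweep(self, wt):
        for kk in np.logspace(-3, 1, 12):
            ss = t.find_steady_states("reduced", dataclasses.replace(wt, k_k=kk))
            assert len(ss) == 1 and ss.stabilities == ["stable"]

    def test_origin_unique_without_production_or_kinase(self):
        p = ReducedParams(V_0=0.0, k_k=0.0)
        ss = t.find_steady_states("reduced", p)
        assert len(ss) == 1
        assert ss.pstars[0] == pytest.approx(0.0, abs=1e-12)
        assert ss.stabilities == ["stable"]

    def test_residuals_below_tolerance(self, t281r, detailed_t281r):
        from tcswitch.models import rhs_for
        for model, p in (("reduced", t281r), ("detailed", detailed_t281r)):
            for s in t.find_steady_states(model, p).states:
                assert np.max(np.abs(rhs_for(model, p)(s))) < 1e-9

    def test_empty_window_rejected(self, t281r):
        with pytest.raises(ValueError):
            t.find_steady_states("reduced", t281r, window=(1.0, 1.0))


class TestOracleEquivalence:
    def test_dense_grid_scan_agrees_on_200_random_draws(self):
        """All roots found, to 1e-6 relative, vs a >=1e5-point sign scan."""
        rng = np.random.default_rng(20250925)
        n_multi = 0
        for _ in range(200):
            p = ReducedParams(
                k_k=10 ** rng.uniform(-4, 1),
                k_p=0.0 if rng.random() < 0.5 else 10 ** rng.uniform(-2, 2),
                V_0=10 ** rng.uniform(-6, -2),
                V_f=10 ** rng.uniform(-2, 0),
                K_f=10 ** rng.uniform(-1, 1),
                h=float(rng.choice([1.0, 2.0])),
                lam=10 ** rng.uniform(-2.3, -1),
            )
            found = t.find_steady_states("reduced", p).pstars
            oracle = dense_grid_roots("reduced", p, 200_000)
            assert found.size == oracle.size, p
            assert np.allclose(found, oracle, rtol=1e-6), p
            n_multi += found.size > 1
        assert n_multi > 10  # the draw family actually exercises bistability


class TestStability:
    def test_middle_root_unstable_outer_stable_by_integration(self, t281r):
        ss = t.find_steady_states("reduced", t281r)
        labels = [stability_by_integration("reduced", t281r, s) for s in ss.states]
        assert labels == ["stable", "unstable", "stable"]
        assert labels == ss.stabilities

    def test_origin_stable_with_dilution_only(self):
        p = ReducedParams(V_0=0.0, k_k=0.0)
        assert t.jacobian_stability("reduced", p, np.zeros(3)) == "stable"

    def test_non_steady_input_rejected(self, t281r):
        with pytest.raises(ValueError):
            t.jacobian_stability("reduced", t281r, np.array([1.0, 1.0, 1.0]))


class TestClassifyRegime:
    def test_three_regimes(self, t281r):
        ss = t.find_steady_states("reduced", t281r)
        assert t.classify_regime(ss, t281r.K_f) == "bistable"
        lo = SteadyStateSet("reduced", [np.array([0, 0, 1e-4])], ["stable"])
        hi = SteadyStateSet("reduced", [np.array([0, 0, 9.0])], ["stable"])
        assert t.classify_regime(lo, 1.0) == "monostable_off"
        assert t.classify_regime(hi, 1.0) == "monostable_on"

    def test_more_than_two_stable_states_is_a_model_violation(self):
        bad = SteadyStateSet("reduced", [np.array([0, 0, v]) for v in (1, 2, 3)],
                             ["stable"] * 3)
        with pytest.raises(ValueError):
            t.classify_regime(bad, 1.0)


class TestBifurcationSweep:
    def test_kinase_sweep_regime_sequence_and_two_folds(self, t281r):
        bt = t.bifurcation_sweep("reduced", t281r, "k_k", np.logspace(-4, 0, 25))
        assert bt.regime_sequence == ["monostable_off", "bistable", "monostable_on"]
        assert len(bt.folds) == 2

    def test_phosphatase_sweep_bistable_only_at_low_kp(self, t281r):
        bt = t.bifurcation_sweep("reduced", t281r, "k_p", np.logspace(-3, 1, 17))
        regs = np.array(bt.regimes)
        assert regs[0] == "bistable"
        assert regs[-1] != "bistable"
        switch = np.nonzero(regs != "bistable")[0][0]
        assert np.all(regs[:switch] == "bistable")
        assert len(bt.folds) >= 1

    def test_lower_v0_extends_bistable_lambda_window_downward(self, t281r):
        grid = np.logspace(-2.6, -0.8, 31)
        lo_edges = {}
        for v0 in (t281r.V_0, 0.1 * t281r.V_0):
            bt = t.bifurcation_sweep("reduced", dataclasses.replace(t281r, V_0=v0),
                                     "lam", grid)
            bist = grid[np.array(bt.regimes) == "bistable"]
            lo_edges[v0] = bist.min()
        assert lo_edges[0.1 * t281r.V_0] < lo_edges[t281r.V_0]

    def test_fold_points_bracket_the_regime_change(self, t281r_folds):
        lo, hi = t281r_folds
        assert 1e-4 < lo < hi < 1.0

    def test_non_monotone_grid_rejected(self, t281r):
        with pytest.raises(ValueError):
            t.bifurcation_sweep("reduced", t281r, "k_k", [0.1, 0.1, 0.2])


class TestHysteresis:
    def test_forward_integration_selects_branch_by_history(self, t281r):
        ss = t.find_steady_states("reduced", t281r)
        lo, mid, hi = ss.pstars
        horizon = 600 * np.log(2) / t281r.lam
        from_low = integrate("reduced", t281r, [0, 0, 0], horizon).y[2, -1]
        big = 1.2 * (t281r.V_0 + t281r.V_f) / t281r.lam
        from_high = integrate("reduced", t281r, [big, big, big], horizon).y[2, -1]
        assert from_low == pytest.approx(lo, rel=1e-3, abs=1e-9)
        assert from_high == pytest.approx(hi, rel=1e-3)


class TestBistabilityScan:
    def test_kp_vf_scan_confines_bistability_to_low_kp(self, t281r):
        rm = t.bistability_scan("reduced", t281r, "k_p", np.logspace(-3, 1, 9),
                                "V_f", np.logspace(-2, 0.5, 7))
        df = rm.to_dataframe()
        bis = df[df.regime == "bistable"]
        assert len(bis) > 0
        assert bis.k_p.max() < df.k_p.max()

    def test_no_feedback_means_no_bistability_anywhere(self, t281r):
        p = dataclasses.replace(t281r, V_f=0.0)
        rm = t.bistability_scan("reduced", p, "k_p", np.logspace(-2, 2, 7),
                                "k_k", np.logspace(-3, 0, 7))
        assert rm.n_bistable == 0

    def test_map_labels_agree_with_find_steady_states(self, t281r):
        xg, yg = np.logspace(-3, 0, 5), np.logspace(-2, 0, 4)
        rm = t.bistability_scan("reduced", t281r, "k_p", xg, "V_f", yg)
        for iy, y in enumerate(yg):
            for ix, x in enumerate(xg):
                ss = t.find_steady_states(
                    "reduced", dataclasses.replace(t281r, k_p=x, V_f=y))
                assert (rm.regimes[iy, ix] == "bistable") == (ss.n_stable == 2)

    def test_scan_reproducible_bit_identically(self, t281r):
        args = ("reduced", t281r, "k_p", np.logspace(-2, 1, 4),
                "V_f", np.logspace(-2, 0, 4))
        a, b = t.bistability_scan(*args), t.bistability_scan(*args)
        assert np.array_equal(a.display, b.display, equal_nan=True)
        assert np.array_equal(a.regimes, b.regimes)

    def test_monostable_display_values_respect_floor(self, t281r):
        rm = t.bistability_scan("reduced", t281r, "k_p", np.logspace(-2, 2, 5),
                                "k_k", np.logspace(-4, -3.5, 3))
        vals = rm.display[~np.isnan(rm.display)]
        assert np.all(vals >= 1e-4)


class TestClampForDisplay:
    def test_values(self):
        assert clamp_for_display(1e-6) == 1e-4
        assert clamp_for_display(0.5) == 0.5
        assert clamp_for_display(1e-4) == 1e-4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            clamp_for_display(-1e-9)
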