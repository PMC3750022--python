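"""Stochastic engine: exactness, determinism, limits, and endpoint statistics."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import tcswitch as t
import tcswitch.ssa as S
from tcswitch.models import detailed_rhs, reduced_rhs


def birth_death_network(beta=5.0, lam=0.05):
    return S.ReactionNetwork(
        species=["Pstar"], stoich=np.array([[1]], dtype=np.int64),
        kinds=np.array([S.K_CONST], dtype=np.int64),
        ridx=np.array([[0, 0]], dtype=np.int64),
        rpar=np.array([[beta, 0, 0, 0]]), omega=1.0, lam=lam)


class TestBuildNetwork:
    def test_t281r_excludes_phosphatase_catalysis(self, t281r, detailed_t281r):
        net = t.build_network("T281R", t281r, 100)
        assert "phosphatase" not in net.labels
        netd = t.build_network("T281R", detailed_t281r, 100, scheme="detailed")
        assert "phosphatase_cat" not in netd.labels
        assert "phosphatase_bind" in netd.labels  # complex may still form

    def test_decoupled_phoq_production_independent_of_pstar(self, decoupled_high_kd):
        net = t.build_network("decoupled", decoupled_high_kd, 100)
        r = net.labels.index("phoQ_production")
        assert net.kinds[r] == S.K_CONST
        a1 = net.propensities([0, 0, 0])[r]
        a2 = net.propensities([0, 0, 10_000])[r]
        assert a1 == a2 > 0

    def test_stoichiometry_conserves_families_except_production(self, detailed_t281r):
        net = t.build_network("T281R", detailed_t281r, 100, scheme="detailed")
        s = net.species
        p_fam = [s.index(x) for x in ("P", "Pstar", "C_t", "C_p")]
        q_fam = [s.index(x) for x in ("Q", "Qstar", "C_t", "C_p")]
        for lab, row in zip(net.labels, net.stoich):
            if lab == "operon_production":
                assert row[p_fam].sum() == 1 and row[q_fam].sum() == 1
            else:
                assert row[p_fam].sum() == 0 and row[q_fam].sum() == 0

    def test_unknown_variant_rejected(self, t281r):
        with pytest.raises(ValueError):
            t.build_network("T281X", t281r, 100)


class TestGillespieRun:
    def test_all_rates_zero_preserves_counts(self, t281r):
        p = dataclasses.replace(t281r, k_k=0.0, V_0=0.0, V_f=0.0)
        net = t.build_network("T281R", p, 100)
        r = t.gillespie_run(net, [7, 5, 3], 4, seed=1, division_policy="none")
        assert np.array_equal(r.final_counts, [7, 5, 3])
        assert np.allclose(r.gen_means, [[7, 5, 3]] * 4)

    def test_zero_generations_is_identity(self, t281r):
        net = t.build_network("T281R", t281r, 100)
        r = t.gillespie_run(net, [1, 2, 3], 0, seed=1)
        assert np.array_equal(r.final_counts, [1, 2, 3])

    def test_seed_determinism(self, t281r):
        net = t.build_network("T281R", t281r, 100)
        a = t.gillespie_run(net, [0, 0, 0], 10, seed=77)
        b = t.gillespie_run(net, [0, 0, 0], 10, seed=77)
        assert np.array_equal(a.final_counts, b.final_counts)
        assert np.array_equal(a.gen_means, b.gen_means)

    def test_negative_init_rejected(self, t281r):
        net = t.build_network("T281R", t281r, 100)
        with pytest.raises(ValueError):
            t.gillespie_run(net, [-1, 0, 0], 1, seed=0)

    def test_birth_death_stationary_mean_and_poisson_variance(self):
        net = birth_death_network(beta=5.0, lam=0.05)  # stationary mean 100
        ens = t.run_ensemble(net, [0], 200, 9, n_generations=30,
                             division_policy="dilution")
        fin = ens["final_Pstar"].to_numpy()
        mean, var = fin.mean(), fin.var(ddof=1)
        se = np.sqrt(100.0 / 200)
        assert abs(mean - 100.0) < 3 * se
        assert 0.7 < var / 100.0 < 1.3  # Poisson: variance = mean

    def test_bistable_state_retention_both_starts(self, t281r, t281r_folds):
        kk_mid = float(np.sqrt(t281r_folds[0] * t281r_folds[1]))
        p = dataclasses.replace(t281r, k_k=kk_mid)
        ss = t.find_steady_states("reduced", p)
        net = t.build_network("T281R", p, 100)
        on_init = np.round(100 * np.asarray(ss.states[-1])).astype(int)
        thr = 100 * np.sqrt(max(ss.pstars[0], 1e-6) * ss.pstars[-1])
        e_on = t.run_ensemble(net, on_init, 40, 21, n_generations=35)
        e_off = t.run_ensemble(net, [0, 0, 0], 40, 22, n_generations=35)
        assert np.mean(e_on["endpoint"] > thr) > 0.9
        assert np.mean(e_off["endpoint"] < thr) > 0.9


class TestRunEnsemble:
    def test_zero_runs_gives_empty_table(self, t281r):
        net = t.build_network("T281R", t281r, 100)
        ens = t.run_ensemble(net, [0, 0, 0], 0, 1)
        assert len(ens) == 0
        assert "endpoint" in ens.columns

    def test_base_seed_determinism(self, t281r):
        net = t.build_network("T281R", t281r, 100)
        a = t.run_ensemble(net, [0, 0, 0], 12, 5, n_generations=8)
        b = t.run_ensemble(net, [0, 0, 0], 12, 5, n_generations=8)
        assert a.equals(b)


class TestDeterministicLimit:
    def test_birth_death_rate_equation(self):
        f = t.deterministic_limit(birth_death_network(beta=5.0, lam=0.05))
        assert f([0.0])[0] == pytest.approx(5.0)
        assert f([100.0])[0] == pytest.approx(0.0)

    def test_detailed_network_limit_matches_detailed_rhs(self, detailed_t281r):
        net = t.build_network("T281R", detailed_t281r, 1000, scheme="detailed")
        f = t.deterministic_limit(net)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 5, 6)
            assert np.allclose(f(x), detailed_rhs(x, detailed_t281r),
                               rtol=1e-10, atol=1e-12)

    def test_reduced_network_limit_matches_reduced_rhs(self, t281r):
        net = t.build_network("T281R", t281r, 100)
        f = t.deterministic_limit(net)
        x = np.array([0.3, 4.0, 2.0])
        assert np.allclose(f(x), reduced_rhs(x, t281r), rtol=1e-10)

    def test_ensemble_mean_tracks_ode_within_three_se(self, t281r):
        """Omega = 1e4, continuous dilution: SSA mean vs ODE at 10 checkpoints."""
        om, n_runs, n_gen = 10_000, 30, 10
        y0 = np.array([0.5, 2.0, 3.0])
        net = t.build_network("T281R", t281r, om)
        traj = np.array([
            t.gillespie_run(net, np.round(y0 * om).astype(int), n_gen,
                            seed=100 + k, division_policy="dilution").pstar_trajectory()
            for k in range(n_runs)]) / om
        mean = traj.mean(axis=0)
        se = traj.std(axis=0, ddof=1) / np.sqrt(n_runs)
        tg = np.log(2) / t281r.lam
        sol = solve_ivp(lambda _, y: reduced_rhs(y, t281r), (0, n_gen * tg), y0,
                        rtol=1e-10, atol=1e-13, dense_output=True)
        for g in range(n_gen):
            ts = np.linspace(g * tg, (g + 1) * tg, 201)
            ode = np.trapezoid(sol.sol(ts)[2], ts) / tg
            assert abs(mean[g] - ode) < 3 * se[g] + 1e-4 * ode


class TestPrimingFraction:
    def test_direct_count(self):
        assert t.priming_fraction([10, 2000, 15, 3000], 500) == 50.0
        assert t.priming_fraction([1, 2, 3], 500) == 0.0

    def test_empty_or_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            t.priming_fraction([], 10)
        with pytest.raises(ValueError):
            t.priming_fraction([1.0], 0.0)


class TestDetectSwitch:
    def test_flat_off_trajectory_has_no_events(self):
        assert t.detect_switch(np.full(30, 1.0), 5, 50) == []

    def test_single_full_band_crossing(self):
        traj = np.concatenate([np.full(10, 100.0), np.full(10, 1.0)])
        assert t.detect_switch(traj, 5, 50) == [("ON->OFF", 10)]

    def test_chatter_inside_band_ignored(self):
        rng = np.random.default_rng(1)
        traj = 25 + 10 * rng.standard_normal(50)  # inside [5, 50] band
        traj = np.clip(traj, 6, 49)
        assert t.detect_switch(traj, 5, 50) == []

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            t.detect_switch([1, 2], 50, 5)


class TestBimodalityReport:
    def test_all_near_off(self):
        rep = t.bimodality_report(np.full(100, 2.0), 2.0, 2000.0)
        assert rep["fraction_off"] == 1.0
        assert rep["fraction_on"] == 0.0 and rep["fraction_intermediate"] == 0.0

    def test_well_separated_mixture_has_no_intermediate_mass(self):
        rng = np.random.default_rng(2)
        e = np.concatenate([rng.poisson(5, 250), rng.poisson(500, 250)])
        rep = t.bimodality_report(e, 5, 500)
        assert rep["fraction_intermediate"] < 0.05
        assert rep["is_bimodal"]

    def test_unimodal_sample_between_references_is_intermediate(self):
        rng = np.random.default_rng(3)
        e = rng.poisson(100, 400)  # geometric midpoint of 10 and 1000
        rep = t.bimodality_report(e, 10, 1000)
        assert rep["fraction_intermediate"] > 0.9
        assert not rep["is_bimodal"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            t.bimodality_report([], 1, 10)
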