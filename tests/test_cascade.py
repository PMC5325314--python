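import dataclasses
import math

import numpy as np
import pytest

from chankin import scenarios as sn, steady_state as ss
from chankin.cascade import (CascadeParams, FeedMode, build_jacobian, build_rhs,
                             initial_state, integrate, steady_state_numeric,
                             time_to_product_fraction)
from chankin.rate_constants import RateValidationError


def rhs_at(params, feed, y):
    return build_rhs(params, feed)(0.0, np.asarray(y, dtype=float))


class TestRhs:
    def test_no_catalyst_only_feed_term(self, base_params):
        p = base_params.with_totals(E1_tot=0.0, E2_tot=0.0, E12_tot=0.0)
        feed = FeedMode("constant_feed", v_S=2.5)
        f = rhs_at(p, feed, initial_state(p, S0=10.0))
        assert f[0] == pytest.approx(2.5)
        assert np.all(f[1:] == 0.0)

    def test_metabolite_mass_balance_closes(self, base_params):
        """Sum of all metabolite-carrying derivatives equals v_S when k_deg=0."""
        rng = np.random.default_rng(3)
        feed = FeedMode("constant_feed", v_S=1.7)
        f = rhs_at(base_params, feed, rng.uniform(0.0, 20.0, 8))
        assert np.sum(f) == pytest.approx(1.7, abs=1e-12)
        # two-site: SE12I carries two metabolites
        p2 = dataclasses.replace(base_params, two_site=True)
        y = rng.uniform(0.0, 5.0, 9)
        f2 = rhs_at(p2, feed, y)
        weights = np.array([1, 1, 1, 1, 1, 1, 1, 2, 1])
        assert np.dot(weights, f2) == pytest.approx(1.7, abs=1e-12)

    def test_limiting_subsystems(self, base_params):
        """E12_tot=0 reproduces the pure cascade; E1=E2=0 the pure channel:
        the unused species stay identically zero and the remaining dynamics
        match the subsystem's own right-hand side."""
        rng = np.random.default_rng(4)
        y = rng.uniform(0.0, 10.0, 8)
        feed = FeedMode("batch")
        y_non = y.copy()
        y_non[4:7] = 0.0  # no complexes
        f_non = rhs_at(base_params.with_totals(E12_tot=0.0), feed, y_non)
        assert np.all(f_non[4:7] == 0.0)
        p = base_params
        S, SE1, I, IE2 = y_non[0], y_non[1], y_non[2], y_non[3]
        E1, E2 = p.E1_tot - SE1, p.E2_tot - IE2
        assert f_non[1] == pytest.approx(p.a1 * E1 * S - (p.d1 + p.k1) * SE1)
        assert f_non[3] == pytest.approx(p.a2 * E2 * I - (p.d2 + p.k2) * IE2)
        y_ch = y.copy()
        y_ch[1] = y_ch[3] = 0.0  # no free-enzyme complexes
        f_ch = rhs_at(base_params.with_totals(E1_tot=0.0, E2_tot=0.0), feed, y_ch)
        assert f_ch[1] == 0.0 and f_ch[3] == 0.0
        E12 = p.E12_tot - y_ch[4] - y_ch[5] - y_ch[6]
        assert f_ch[4] == pytest.approx(p.a_ch * E12 * y_ch[0] - (p.d_ch + p.k1_ch) * y_ch[4])

    def test_negative_parameters_rejected(self):
        with pytest.raises(RateValidationError):
            CascadeParams(a1=-1.0, d1=1.0, k1=1.0, a2=1.0, d2=1.0, k2=1.0,
                          a_ch=1.0, d_ch=1.0, k_ch=1.0)

    def test_fairness_defaults(self, base_params):
        assert base_params.k1_ch == base_params.k1
        assert base_params.k2_ch == base_params.k2

    @pytest.mark.parametrize("two_site", [False, True])
    @pytest.mark.parametrize("mode", ["batch", "constant_substrate"])
    def test_jacobian_matches_finite_differences(self, base_params, two_site, mode):
        p = dataclasses.replace(base_params, two_site=two_site, k_deg=0.3, kbar1=0.01)
        feed = FeedMode(mode, S_fixed=90.0 if mode == "constant_substrate" else None)
        rhs, jac = build_rhs(p, feed), build_jacobian(p, feed)
        n = 9 if two_site else 8
        rng = np.random.default_rng(11)
        y = rng.uniform(0.1, 20.0, n)
        J = jac(0.0, y)
        h = 1e-6
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            col = (rhs(0.0, y + e) - rhs(0.0, y - e)) / (2 * h)
            assert np.allclose(J[:, j], col, atol=1e-6)


class TestIntegrate:
    def test_batch_runs_to_complete_conversion(self, nonchanneled_params):
        traj = integrate(nonchanneled_params, FeedMode("batch"),
                         initial_state(nonchanneled_params, S0=50.0), t_end=2e3)
        assert traj["P"][-1] == pytest.approx(50.0, rel=1e-6)
        assert traj["S"][-1] < 1e-4 and traj["I"][-1] < 1e-4

    def test_conservation_along_trajectory(self, base_params):
        traj = integrate(base_params, FeedMode("batch"),
                         initial_state(base_params, S0=90.0), t_end=100.0)
        errs = traj.conservation_errors()
        assert errs["metabolite"] < 1e-8
        assert errs["E1"] < 1e-8 and errs["E2"] < 1e-8 and errs["E12"] < 1e-8

    def test_strong_degradation_drains_intermediate(self, base_params):
        p = dataclasses.replace(base_params.with_totals(E2_tot=0.0, E12_tot=0.0),
                                k_deg=1e6)
        traj = integrate(p, FeedMode("batch"), initial_state(p, S0=90.0), t_end=50.0)
        assert np.max(traj["I"]) < 1e-3
        assert np.max(traj.v_P) == pytest.approx(0.0, abs=1e-12)


class TestSteadyStateNumeric:
    def test_matches_pool_formula_below_threshold(self, nonchanneled_params):
        out = steady_state_numeric(nonchanneled_params,
                                   FeedMode("constant_substrate", S_fixed=90.0))
        assert out.verdict == "converged"
        res = ss.v_nonchanneled(nonchanneled_params, 90.0)
        assert out.state[2] == pytest.approx(res.I_ss, rel=1e-6)
        assert out.v_P == pytest.approx(res.v, rel=1e-8)

    def test_diverging_verdict_above_threshold(self, nonchanneled_params):
        p = dataclasses.replace(nonchanneled_params, E2_tot=40.0)
        thr = ss.s_threshold(p)
        out = steady_state_numeric(p, FeedMode("constant_substrate", S_fixed=1.5 * thr))
        assert out.verdict == "diverging"

    def test_pure_channeled_never_diverges(self, channeled_params):
        out = steady_state_numeric(channeled_params,
                                   FeedMode("constant_substrate", S_fixed=1e5))
        assert out.verdict == "converged"

    def test_batch_mode_rejected(self, base_params):
        with pytest.raises(ValueError):
            steady_state_numeric(base_params, FeedMode("batch"))


class TestTimeToProductFraction:
    def test_small_alpha_gives_small_time(self, nonchanneled_params):
        t = time_to_product_fraction(nonchanneled_params, S0=90.0, alpha=1e-6)
        assert 0 < t < 0.5

    def test_monotone_in_alpha(self, nonchanneled_params):
        ts = [time_to_product_fraction(nonchanneled_params, 90.0, a)
              for a in (0.1, 0.5, 0.9)]
        assert ts[0] < ts[1] < ts[2]

    def test_alpha_one_unreachable(self, nonchanneled_params):
        with pytest.raises(ValueError):
            time_to_product_fraction(nonchanneled_params, 90.0, 1.0)

    def test_doubling_enzymes_halves_time_at_low_substrate(self, base_scenario):
        """With S0 << K_M the kinetics are linear in enzyme, so doubling all
        totals halves the conversion time to within a few percent (enzyme
        levels low enough that conversion is slow next to the fixed
        complex-equilibration lag)."""
        p = base_scenario.params.with_totals(E1_tot=5.0, E2_tot=5.0, E12_tot=0.0)
        S0 = 0.5  # well below K_M ~ 161 nM
        t1 = time_to_product_fraction(p, S0, 0.5)
        p2 = p.with_totals(E1_tot=10.0, E2_tot=10.0)
        t2 = time_to_product_fraction(p2, S0, 0.5)
        assert t1 / t2 == pytest.approx(2.0, rel=0.05)


def test_two_site_high_substrate_limit(base_params):
    """With two metabolites allowed in the complex, saturation velocity is
    k2 k_ch E12/(k2 + k_ch)."""
    p = dataclasses.replace(base_params.with_totals(E1_tot=0.0, E2_tot=0.0),
                            two_site=True)
    out = steady_state_numeric(p, FeedMode("constant_substrate",
                                           S_fixed=1e6 * base_params.KM_ch))
    want = ss.v_max(base_params).v_ch_max_two_site
    assert out.v_P == pytest.approx(want, rel=1e-3)
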