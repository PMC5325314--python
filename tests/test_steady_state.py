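import dataclasses
import math

import numpy as np
import pytest

from chankin import scenarios as sn, steady_state as ss


class TestChanneledVelocity:
    def test_zero_substrate(self, base_params):
        assert ss.v_channeled(base_params, 0.0) == 0.0

    def test_reference_value(self, base_params):
        assert ss.v_channeled(base_params, 90.0) == pytest.approx(14.1774, abs=5e-4)

    def test_saturation_limit(self, base_params):
        """|v_ch/v_ch_max - 1| < 1e-6 at S = 1e9 K_M^ch."""
        v = ss.v_channeled(base_params, 1e9 * base_params.KM_ch)
        assert abs(v / ss.v_max(base_params).v_ch_max - 1) < 1e-6

    def test_negative_substrate_rejected(self, base_params):
        with pytest.raises(ValueError):
            ss.v_channeled(base_params, -1.0)


class TestNonChanneledVelocity:
    def test_reference_value(self, base_params):
        res = ss.v_nonchanneled(base_params, 90.0)
        assert res.v == pytest.approx(26.8805, abs=5e-4)
        assert res.regime == "first-limiting"
        assert res.I_ss == pytest.approx(90.0, rel=1e-12)

    def test_balanced_capacities_never_diverge(self, base_params):
        """k1 E1 = k2 E2 puts the threshold at infinity: Michaelis-Menten
        branch at every substrate level."""
        assert math.isinf(ss.s_threshold(base_params))
        res = ss.v_nonchanneled(base_params, 1e9)
        assert res.regime == "first-limiting"

    def test_saturated_branch_above_threshold(self, base_params):
        p = dataclasses.replace(base_params, E2_tot=40.0)
        thr = ss.s_threshold(p)
        res = ss.v_nonchanneled(p, 2 * thr)
        assert res.v == pytest.approx(p.k2 * 40.0)
        assert math.isinf(res.I_ss) and res.regime == "diverging"

    def test_pool_formula_dash_variant(self):
        """k1 E1 = k2 E2 with k2 = 1, E2 = 75: threshold infinite, finite pool."""
        p = sn.mapk_scenario(k2=1.0, E2_tot=75.0).params
        assert math.isinf(ss.s_threshold(p))
        res = ss.v_nonchanneled(p, 90.0)
        assert res.regime == "first-limiting"


class TestThreshold:
    def test_factor_two_identity(self, base_params):
        """k1 E1 = 2 k2 E2 puts the threshold exactly at K_M^(1)."""
        p = dataclasses.replace(base_params, E2_tot=25.0)
        assert ss.s_threshold(p) == pytest.approx(p.KM1, rel=1e-12)

    def test_reference_value(self, base_params):
        p = dataclasses.replace(base_params, E2_tot=40.0)
        assert ss.s_threshold(p) == pytest.approx(644.4444444, rel=1e-9)


class TestVMax:
    def test_reference_values(self, base_params):
        v = ss.v_max(base_params)
        assert v.v_non_max == pytest.approx(75.0)
        assert v.v_ch_max == pytest.approx(21.42857142857, rel=1e-10)
        assert v.v_ch_max_two_site == pytest.approx(30.0)

    def test_fast_channeling_limit(self, base_params):
        p = dataclasses.replace(base_params, k_ch=1e12)
        v = ss.v_max(p)
        k1, k2, E = base_params.k1, base_params.k2, base_params.E12_tot
        assert v.v_ch_max == pytest.approx(E / (1 / k1 + 1 / k2), rel=1e-9)
        assert v.v_ch_max_two_site == pytest.approx(k2 * E, rel=1e-9)

    def test_channeling_never_faster_in_saturation(self):
        """Harmonic-sum inequality: v_ch_max < v_non_max whenever E12 = E1,
        for any positive rates (1000 random draws)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k1, k2, kc = np.exp(rng.uniform(-3, 3, size=3))
            assert 1.0 / (1 / k1 + 1 / kc + 1 / k2) < k1


class TestLowSubstrate:
    def test_equal_parameters_equal_velocities(self, base_params):
        v_non, v_ch = ss.low_s_velocities(base_params, 1e-3)
        assert v_ch == pytest.approx(v_non, rel=1e-12)

    def test_lower_gamma_ch_accelerates(self):
        """K_M^ch < K_M^(1) iff gamma_ch < gamma_1 at equal micro constants."""
        sc = sn.mapk_scenario(gamma_ch=0.2)
        v_non, v_ch = ss.low_s_velocities(sc.params, 1e-3)
        assert v_ch > v_non
        sc2 = sn.mapk_scenario(gamma_ch=5.0)
        v_non2, v_ch2 = ss.low_s_velocities(sc2.params, 1e-3)
        assert v_ch2 < v_non2

    def test_first_order_limit_of_full_formulas(self, base_params):
        S = 1e-3 * base_params.KM1
        v_non, v_ch = ss.low_s_velocities(base_params, S)
        assert ss.v_channeled(base_params, S) == pytest.approx(v_ch, rel=5e-3)
        assert ss.v_nonchanneled(base_params, S).v == pytest.approx(v_non, rel=5e-3)


class TestMixedPool:
    def test_equal_enzymes_pool_independent_of_channeling(self, base_params):
        vals = [ss.iss_mixed(base_params, 90.0, x) for x in (0.0, 0.4, 0.8)]
        assert np.allclose(vals, 90.0, rtol=1e-12)

    def test_e2_abundant_pool_decreases(self):
        p = sn.mapk_scenario(k2=1.0, E2_tot=75.0).params
        i0 = ss.iss_mixed(p, 90.0, 0.0)
        i5 = ss.iss_mixed(p, 90.0, 0.5)
        assert i0 == pytest.approx(69.31, abs=0.01)
        assert i5 == pytest.approx(45.61, abs=0.01)
        assert i5 < i0

    def test_e1_abundant_pool_increases_and_diverges(self):
        p = sn.mapk_scenario(k2=2.0, E2_tot=37.5).params
        grid = np.linspace(0.0, 0.9, 10)
        vals = [ss.iss_mixed(p, 90.0, x) for x in grid]
        assert np.all(np.diff(vals) > 0)
        # the single-enzyme subsystem crosses its threshold at finite x_ch
        assert math.isinf(ss.iss_mixed(p, 1500.0, 0.9))

    def test_pool_sign_law(self):
        """d I_ss/d x_ch is 0, >0, <0 for E1 =, >, < E2 under k1 E1 = k2 E2."""
        for k2, E2, sign in ((1.5, 50.0, 0), (2.0, 37.5, +1), (1.0, 75.0, -1)):
            p = sn.mapk_scenario(k2=k2, E2_tot=E2).params
            d = (ss.iss_mixed(p, 90.0, 0.41) - ss.iss_mixed(p, 90.0, 0.39)) / 0.02
            if sign == 0:
                assert abs(d) < 1e-9
            else:
                assert np.sign(d) == sign

    def test_invalid_x_ch(self, base_params):
        with pytest.raises(ValueError):
            ss.iss_mixed(base_params, 90.0, 1.0)


class TestDegradation:
    def test_zero_rate_recovers_baseline(self, base_params):
        I0, v0 = ss.solve_degradation(base_params, 90.0, 0.0)
        res = ss.v_nonchanneled(base_params, 90.0)
        assert I0 == pytest.approx(res.I_ss, rel=1e-12)
        assert v0 == pytest.approx(res.v, rel=1e-12)

    def test_strong_degradation_drains_everything(self, base_params):
        I, v = ss.solve_degradation(base_params, 90.0, 1e9)
        assert I < 1e-6 and v < 1e-3

    def test_residual_of_root(self, base_params):
        """The root satisfies the steady-state balance to < 1e-10 nM/s."""
        for k_deg in (1e-3, 0.1, 1.0, 10.0):
            I, v = ss.solve_degradation(base_params, 90.0, k_deg)
            v0 = ss.v_nonchanneled(base_params, 90.0).v
            cap = base_params.k2 * base_params.E2_tot
            resid = v0 - cap * I / (base_params.KM2 + I) - k_deg * I
            assert abs(resid) < 1e-10
            assert v == pytest.approx(v0 - k_deg * I, rel=1e-12)

    def test_crossing_with_channeled_velocity(self, base_params):
        """v_non(k_deg) decreases and crosses v_ch at k_deg of order 1/s."""
        v_ch = ss.v_channeled(base_params, 90.0)
        grid = np.geomspace(1e-3, 1e2, 30)
        v = np.array([ss.solve_degradation(base_params, 90.0, k)[1] for k in grid])
        assert np.all(np.diff(v) < 0)
        crossing = np.interp(0.0, -(v - v_ch), grid)
        assert 0.1 < crossing < 100.0


class TestReversible:
    def test_zero_reverse_rate_recovers_baseline(self, base_params):
        I, v = ss.solve_reversible(base_params, 90.0, 0.0)
        res = ss.v_nonchanneled(base_params, 90.0)
        assert (I, v) == (res.I_ss, res.v)

    def test_velocity_decreases_with_reversibility(self, base_params):
        kbars = np.geomspace(1e-4, 10.0, 25) * base_params.a1
        vs = np.array([ss.solve_reversible(base_params, 90.0, kb)[1] for kb in kbars])
        v0 = ss.v_nonchanneled(base_params, 90.0).v
        assert np.all(vs < v0)
        assert np.all(np.diff(vs) < 0)

    def test_velocity_ratio_independent_of_enzyme_scale(self, base_params):
        """v_non/v_ch is invariant under x10 scaling of all totals."""
        kbar = 0.5 * base_params.a1
        _, v1 = ss.solve_reversible(base_params, 90.0, kbar)
        r1 = v1 / ss.v_channeled(base_params, 90.0)
        p10 = base_params.with_totals(E1_tot=500.0, E2_tot=500.0, E12_tot=500.0)
        _, v10 = ss.solve_reversible(p10, 90.0, kbar)
        r10 = v10 / ss.v_channeled(p10, 90.0)
        assert r10 == pytest.approx(r1, rel=1e-10)

    def test_consistency_of_both_equations(self, base_params):
        """The root satisfies the forward-flux and consumption forms at once."""
        kbar = 0.2 * base_params.a1
        I, v = ss.solve_reversible(base_params, 90.0, kbar)
        p = base_params
        KbM1 = (p.k1 + p.d1) / kbar
        v16 = (p.E1_tot * (p.k1 * 90.0 / p.KM1 - p.d1 * I / KbM1)
               / (1 + 90.0 / p.KM1 + I / KbM1))
        assert v == pytest.approx(v16, rel=1e-10)


def test_closed_forms_match_ode_on_ensemble(small_ensemble):
    """Core analytic <-> numeric equivalence on a seeded random ensemble."""
    from chankin.cascade import steady_state_numeric

    for sc in small_ensemble:
        p, S = sc.params, sc.S0
        och = steady_state_numeric(p.with_totals(E1_tot=0.0, E2_tot=0.0), sc.feed)
        assert och.verdict == "converged"
        assert och.v_P == pytest.approx(ss.v_channeled(p, S), rel=1e-4)
        onon = steady_state_numeric(p.with_totals(E12_tot=0.0), sc.feed)
        assert onon.verdict == "converged"
        assert onon.v_P == pytest.approx(ss.v_nonchanneled(p, S).v, rel=1e-4)
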