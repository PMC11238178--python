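"""Unit and property tests for the PQN neuron model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pqnfly.pqn import (
    NeuronPopulationState,
    PQNParameters,
    derive_dependent_params,
    detect_spike,
    eval_piecewise,
    simulate_trace,
    step_pn,
    step_single,
    step_two_comp,
    transform_input,
    update_homeostasis,
)


def make_params(**kw):
    defaults = dict(
        tau=1.0, phi=1.0, epsilon=1.0,
        a_fn=1.0, b_fn=0.0, c_fn=0.0, a_fp=1.0,
        a_gn=1.0, b_gn=0.0, c_gn=0.0, a_gp=1.0, r_g=0.0,
        a_hn=1.0, b_hn=0.0, c_hn=0.0, a_hp=1.0, r_h=0.0,
    )
    defaults.update(kw)
    return PQNParameters(**defaults)


class TestDeriveDependentParams:
    def test_identical_branches_are_unchanged(self):
        p = make_params(a_fn=1.5, b_fn=-0.7, c_fn=0.3, a_fp=1.5)
        assert p.b_fp == pytest.approx(-0.7)
        assert p.c_fp == pytest.approx(0.3)

    def test_f_branch_values_and_slopes_match_by_hand(self):
        # left branch (v+1)^2 - matching right branch with double curvature
        p = make_params(a_fn=1.0, b_fn=-1.0, c_fn=0.0, a_fp=2.0)
        assert p.b_fp == pytest.approx(-0.5)
        assert p.c_fp == pytest.approx(0.5)
        eps = 1e-7
        left, right = eval_piecewise("f", -eps, p), eval_piecewise("f", 0.0, p)
        assert left == pytest.approx(1.0, abs=1e-6)
        assert right == pytest.approx(1.0)
        dleft = (eval_piecewise("f", -eps, p) - eval_piecewise("f", -2 * eps, p)) / eps
        dright = (eval_piecewise("f", 2 * eps, p) - eval_piecewise("f", eps, p)) / eps
        assert dleft == pytest.approx(2.0, abs=1e-5)
        assert dright == pytest.approx(2.0, abs=1e-5)

    def test_g_coefficients_by_hand(self):
        p = make_params(a_gn=1.0, b_gn=0.0, c_gn=0.0, a_gp=1.0, r_g=0.5)
        assert p.b_gp == pytest.approx(0.0)
        assert p.c_gp == pytest.approx(0.0)

    @pytest.mark.parametrize("zero_field", ["a_fp", "a_gp", "a_hp"])
    def test_zero_right_curvature_rejected(self, zero_field):
        with pytest.raises(ValueError):
            make_params(**{zero_field: 0.0})

    def test_m0_above_m1_rejected(self):
        with pytest.raises(ValueError):
            make_params(m0=2.0, m1=1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        a_n=st.floats(-3, 3), b_n=st.floats(-2, 2), c_n=st.floats(-2, 2),
        a_p=st.floats(-3, 3).filter(lambda x: abs(x) > 1e-3),
        r=st.floats(-1, 1),
    )
    def test_nullclines_c1_continuous_at_branch_points(self, a_n, b_n, c_n, a_p, r):
        p = make_params(
            a_fn=a_n, b_fn=b_n, c_fn=c_n, a_fp=a_p,
            a_gn=a_n, b_gn=b_n, c_gn=c_n, a_gp=a_p, r_g=r,
            a_hn=a_n, b_hn=b_n, c_hn=c_n, a_hp=a_p, r_h=r,
        )
        eps = 1e-8
        for which, rb in (("f", 0.0), ("g", r), ("h", r)):
            lo = eval_piecewise(which, rb - eps, p)
            hi = eval_piecewise(which, rb, p)
            assert hi == pytest.approx(lo, abs=1e-5)
            dlo = (eval_piecewise(which, rb - eps, p)
                   - eval_piecewise(which, rb - 2 * eps, p)) / eps
            dhi = (eval_piecewise(which, rb + 2 * eps, p)
                   - eval_piecewise(which, rb + eps, p)) / eps
            assert dhi == pytest.approx(dlo, abs=1e-4)

    def test_stored_derived_coefficients_recomputable(self):
        p = make_params(a_fn=2.0, b_fn=-1.0, c_fn=0.5, a_fp=-1.0)
        assert p.derived_consistent()
        assert not derive_dependent_params(p).b_fp != p.b_fp  # same values


class TestEvalPiecewise:
    def test_left_branch_substitution(self):
        p = make_params()
        assert eval_piecewise("f", -1.0, p) == pytest.approx(1.0)

    def test_h_continuous_at_branch_point(self):
        p = make_params(a_hn=2.0, b_hn=-0.3, c_hn=0.1, a_hp=-1.0, r_h=0.4)
        left_form = 2.0 * (0.4 - (-0.3)) ** 2 + 0.1
        assert eval_piecewise("h", 0.4, p) == pytest.approx(left_form)

    def test_unknown_nullcline_rejected(self):
        with pytest.raises(ValueError):
            eval_piecewise("z", 0.0, make_params())


class TestTransformInput:
    @pytest.mark.parametrize(
        "I,expected", [(1.0, 0.5), (-3.0, -0.5), (2.0, 1.0), (5.0, 1.0)]
    )
    def test_clamped_scaling(self, I, expected):
        p = make_params(k_I=0.5, m0=-1.0, m1=2.0)
        assert transform_input(I, p) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20))
    def test_monotone_nondecreasing(self, xs):
        p = make_params(k_I=0.7, m0=-2.0, m1=3.0)
        xs = np.sort(np.asarray(xs))
        ys = transform_input(xs, p)
        assert np.all(np.diff(ys) >= 0)
        assert np.all(ys >= 0.7 * -2.0) and np.all(ys <= 0.7 * 3.0)


class TestDetectSpike:
    @pytest.mark.parametrize(
        "v_old,v_new,expected",
        [(-0.1, 0.0, True), (0.1, 0.2, False), (-0.2, -0.1, False),
         (-5.0, 3.0, True), (0.0, 1.0, False)],
    )
    def test_negative_to_nonnegative_crossing(self, v_old, v_new, expected):
        assert bool(detect_spike(v_old, v_new)) is expected


class TestStepSingle:
    def test_fixed_point_is_stationary(self):
        # v=-1 with n=g(-1), q=h(-1), I_b0 balancing f(-1)
        p = make_params(epsilon=1.0, I_b0=0.0, k_I=0.0)
        st_ = NeuronPopulationState.zeros(1)
        st_.v[:] = -1.0
        st_.n[:] = eval_piecewise("g", -1.0, p)
        st_.q[:] = eval_piecewise("h", -1.0, p)
        # choose I_b0 so dv = 0 at this point
        p = make_params(
            epsilon=1.0, k_I=0.0,
            I_b0=-(eval_piecewise("f", -1.0, p) - st_.n[0] - st_.q[0]),
        )
        v0, n0, q0 = st_.v.copy(), st_.n.copy(), st_.q.copy()
        st_, _ = step_single(st_, p, 0.0, 1e-3)
        assert st_.v == pytest.approx(v0)
        assert st_.n == pytest.approx(n0)
        assert st_.q == pytest.approx(q0)

    def test_hand_euler_step(self):
        p = make_params(tau=1.0, phi=1.0, epsilon=1.0, I_b0=0.0, k_I=0.0)
        st_ = NeuronPopulationState.zeros(1)
        st_.v[:] = -1.0
        st_, _ = step_single(st_, p, 0.0, 1e-3)
        assert st_.v[0] == pytest.approx(-1.0 + 1e-3 * 1.0)  # f(-1)=1
        assert st_.n[0] == pytest.approx(1e-3 * 1.0)          # g(-1)=1
        assert st_.q[0] == pytest.approx(1e-3 * 1.0)          # h(-1)=1

    def test_zero_dt_leaves_state(self):
        p = make_params()
        st_ = NeuronPopulationState.zeros(3)
        st_.v[:] = [-1.0, -0.5, 0.3]
        v0 = st_.v.copy()
        st_, _ = step_single(st_, p, 1.0, 0.0)
        assert np.array_equal(st_.v, v0)

    def test_all_zero_system_stays_at_origin(self):
        p = make_params(a_gn=0.0, a_hn=0.0, b_gn=0.0, b_hn=0.0,
                        c_gn=0.0, c_hn=0.0, k_I=0.0)
        p = make_params(a_fn=1.0, b_fn=0.0, c_fn=0.0, a_fp=1.0,
                        a_gn=1.0, a_gp=1.0, a_hn=1.0, a_hp=1.0, k_I=0.0)
        st_ = NeuronPopulationState.zeros(2)
        for _ in range(100):
            st_, _ = step_single(st_, p, 0.0, 1e-3)
        assert np.all(st_.v == 0) and np.all(st_.n == 0) and np.all(st_.q == 0)


class TestStepTwoComp:
    def test_soma_relaxes_to_closed_form_fixed_point(self):
        # decoupled soma: dv_s/dt = (theta/tau)(-2 v_s + 1) -> v_s* = 0.5
        p = make_params(variant="two_comp", epsilon=0.0, k_0=0.0,
                        theta=1.0, alpha_leak=2.0, I_b1=1.0, k_r=0.0, k_I=0.0)
        st_ = NeuronPopulationState.zeros(1)
        for _ in range(8000):
            st_, _ = step_two_comp(st_, p, 0.0, 1e-3)
        assert st_.v_s[0] == pytest.approx(0.5, abs=1e-3)

    def test_equal_compartments_have_no_internal_current(self):
        p = make_params(variant="two_comp", k_0=1.0, theta=1.0,
                        alpha_leak=0.0, k_I=0.0)
        st_ = NeuronPopulationState.zeros(1)
        st_.v[:] = st_.v_s[:] = -0.7
        st_, _ = step_two_comp(st_, p, 0.0, 1e-3)
        # soma unchanged: I_c = 0 and no leak/bias
        assert st_.v_s[0] == pytest.approx(-0.7)

    def test_internal_current_transfers_charge(self):
        p = make_params(variant="two_comp", k_0=1.0, theta=1.0,
                        alpha_leak=0.0, I_b1=0.0, k_I=0.0,
                        a_fn=1.0, b_fn=0.0, c_fn=0.0, a_fp=1.0)
        st_ = NeuronPopulationState.zeros(1)
        st_.v[:] = 1.0
        st_, _ = step_two_comp(st_, p, 0.0, 1e-3)
        # I_c = 1: soma gains dt*I_c; axon loses it on top of f(v)=1
        assert st_.v_s[0] == pytest.approx(1e-3)
        assert st_.v[0] == pytest.approx(1.0 + 1e-3 * (1.0 - 0.0 - 1.0))

    def test_euler_matches_exponential_solution_as_dt_shrinks(self):
        # closed form: v_s(t) = 0.5 (1 - exp(-2t)) for theta=tau=1, alpha=2, I_b1=1
        p = make_params(variant="two_comp", epsilon=0.0, k_0=0.0,
                        theta=1.0, alpha_leak=2.0, I_b1=1.0, k_r=0.0, k_I=0.0)
        t_end = 1.0
        errs = []
        for dt in (1e-2, 1e-3):
            st_ = NeuronPopulationState.zeros(1)
            for _ in range(int(t_end / dt)):
                st_, _ = step_two_comp(st_, p, 0.0, dt)
            exact = 0.5 * (1 - np.exp(-2 * t_end))
            errs.append(abs(st_.v_s[0] - exact))
        assert errs[1] < errs[0] / 5  # first-order convergence
        assert errs[1] < 1e-3


class TestStepPN:
    def test_open_gate_matches_two_comp(self):
        kw = dict(theta=1.0, alpha_leak=1.0, k_0=0.5, k_I=1.0, m0=-5.0, m1=5.0)
        p_pn = make_params(variant="pn", **kw)
        p_tc = make_params(variant="two_comp", **kw)
        a = NeuronPopulationState.zeros(1, u_init=1.0)
        b = NeuronPopulationState.zeros(1)
        for _ in range(50):
            a, _ = step_pn(a, p_pn, 0.8, 1e-3)
            b, _ = step_two_comp(b, p_tc, 0.8, 1e-3)
        assert a.v[0] == pytest.approx(b.v[0])
        assert a.v_s[0] == pytest.approx(b.v_s[0])

    def test_closed_gate_ignores_drive(self):
        p = make_params(variant="pn", k_I=1.0, m0=-5.0, m1=5.0)
        a = NeuronPopulationState.zeros(1, u_init=0.0)
        b = NeuronPopulationState.zeros(1, u_init=0.0)
        a, _ = step_pn(a, p, 100.0, 1e-3)
        b, _ = step_pn(b, p, 0.0, 1e-3)
        assert a.v[0] == b.v[0]

    def test_half_gate_halves_drive(self):
        p = make_params(variant="pn", k_I=1.0, m0=-5.0, m1=5.0,
                        a_fn=1.0, b_fn=0.0, c_fn=0.0, a_fp=1.0)
        st_ = NeuronPopulationState.zeros(1, u_init=0.5)
        st_, _ = step_pn(st_, p, 2.0, 1e-3)
        # dv = dt * (f(0) - 0 + 0 + 0.5*2 - 0) = dt * 1
        assert st_.v[0] == pytest.approx(1e-3 * 1.0)


class TestHomeostasis:
    def test_on_target_rate_leaves_gain(self):
        p = make_params(variant="pn", kappa=0.01, F_t=10.0)
        st_ = NeuronPopulationState.zeros(1, u_init=0.5)
        st_.spike_count_window[:] = 10
        st_ = update_homeostasis(st_, p)
        assert st_.u[0] == pytest.approx(0.5)
        assert st_.spike_count_window[0] == 0

    def test_silent_neuron_gains(self):
        p = make_params(variant="pn", kappa=0.01, F_t=10.0, tau=1.0)
        st_ = NeuronPopulationState.zeros(1, u_init=0.5)
        st_ = update_homeostasis(st_, p)
        assert st_.u[0] == pytest.approx(0.6)  # += 0.01 * 10

    def test_gain_clamped_at_bounds(self):
        p = make_params(variant="pn", kappa=0.05, F_t=10.0)
        st_ = NeuronPopulationState.zeros(1, u_init=0.9)
        st_ = update_homeostasis(st_, p)
        assert st_.u[0] == 1.0
        st_.spike_count_window[:] = 1000
        st_ = update_homeostasis(st_, p)
        st_.spike_count_window[:] = 1000
        st_ = update_homeostasis(st_, p)
        assert st_.u[0] == 0.0

    def test_gain_monotone_under_persistent_overshoot(self):
        p = make_params(variant="pn", kappa=0.001, F_t=5.0)
        st_ = NeuronPopulationState.zeros(1, u_init=0.8)
        us = []
        for _ in range(20):
            st_.spike_count_window[:] = 50
            st_ = update_homeostasis(st_, p)
            us.append(st_.u[0])
        assert np.all(np.diff(us) <= 0)
        assert np.all((0 <= np.array(us)) & (np.array(us) <= 1))


class TestSimulateTrace:
    def excitable(self, **kw):
        kw.setdefault("tau", 0.008)
        kw.setdefault("phi", 2.0)
        kw.setdefault("epsilon", 0.0)
        return make_params(
            a_fn=1.0, b_fn=-1.0, c_fn=0.0, a_fp=-1.0,
            a_gn=0.0, b_gn=0.0, c_gn=0.0, a_gp=4.0, r_g=0.0,
            a_hn=0.0, b_hn=0.0, c_hn=0.0, a_hp=1.0, r_h=0.0,
            I_b0=-0.25, k_I=1.0, m0=0.0, m1=10.0, **kw,
        )

    def test_determinism_and_causality(self):
        p = self.excitable()
        I = np.full(2000, 1.0)
        short = simulate_trace(p, I[:1000])
        long = simulate_trace(p, I)
        assert np.array_equal(short["v"], long["v"][:1000])

    def test_spike_count_matches_posthoc_crossing_scan(self):
        p = self.excitable()
        tr = simulate_trace(p, np.full(3000, 2.0))
        v = np.concatenate([[0.0], tr["v"]])
        crossings = np.count_nonzero((v[:-1] < 0) & (v[1:] >= 0))
        assert crossings == tr["spiked"].sum()
        assert crossings > 10  # it does fire

    def test_two_compartment_routes_input_to_soma(self):
        p = self.excitable(variant="two_comp", theta=1.0, alpha_leak=1.0,
                           I_b1=0.0, k_0=0.0, k_r=1.0)
        tr = simulate_trace(p, np.full(500, 1.0))
        # soma charges toward I_r / alpha = 1
        assert tr["v_s"][-1] > 0.5

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(self.excitable(), np.array([1.0, np.nan]))

    def test_halving_dt_converges_on_the_settled_state(self):
        # subthreshold drive: after the initial transient the neuron settles
        # at a dt-independent fixed point; the settled error shrinks with dt
        p = self.excitable()
        finals = {}
        for dt in (1e-3, 5e-4, 2.5e-4):
            tr = simulate_trace(p, np.full(int(0.5 / dt), 0.1), dt=dt)
            finals[dt] = tr["v"][-1]
        ref = finals[2.5e-4]
        assert abs(finals[5e-4] - ref) <= abs(finals[1e-3] - ref) + 1e-12
        assert finals[1e-3] == pytest.approx(ref, abs=1e-2)
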