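"""Dopamine-gated eligibility-trace plasticity rules and engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgtlearn import network as nw
from cbgtlearn import plasticity as pl


@pytest.fixture()
def params():
    return pl.PlasticityParams()


class TestTraces:
    def test_pure_decay(self, params):
        s = pl.SynapseState(a_pre=1.0)
        for _ in range(100):
            pl.update_traces(s, False, False, 1.0, params)
        assert s.a_pre == pytest.approx(np.exp(-100 / params.tau_pre_ms))

    def test_spike_jump_matches_impulse_integral(self, params):
        """A single presynaptic spike lifts A_PRE by Delta/tau — the exact
        integral of the printed impulse ODE across the delta, confirmed by
        a fine-step oracle on the continuous equation."""
        s = pl.SynapseState()
        pl.update_traces(s, True, False, 0.01, params)
        jump = params.delta_pre / params.tau_pre_ms
        # fine-step oracle: integrate dA/dt = (Delta*delta(t) - A)/tau with
        # the delta smeared over a tiny window eps
        eps, steps = 1e-4, 1000
        a = 0.0
        for _ in range(steps):
            x = 1.0 / eps  # delta approximation of unit mass over eps
            a += (eps / steps) * (params.delta_pre * x - a) / params.tau_pre_ms
        assert s.a_pre == pytest.approx(jump, rel=1e-6)
        assert a == pytest.approx(jump, rel=1e-2)

    def test_post_spike_leaves_pre_trace_unchanged(self, params):
        s = pl.SynapseState(a_pre=0.4)
        before = s.a_pre * np.exp(-1.0 / params.tau_pre_ms)
        pl.update_traces(s, False, True, 1.0, params)
        assert s.a_pre == pytest.approx(before)
        assert s.a_post > 0


class TestEligibility:
    def test_pure_decay(self, params):
        s = pl.SynapseState(e=0.7)
        pl.update_eligibility(s, False, False, 8.0, params)
        assert s.e == pytest.approx(0.7 * np.exp(-8.0 / params.tau_e_ms))

    def test_post_after_pre_increases(self, params):
        s = pl.SynapseState(a_pre=0.5, a_post=0.0)
        pl.update_eligibility(s, False, True, 0.01, params)
        assert s.e > 0

    def test_pre_after_post_decreases(self, params):
        s = pl.SynapseState(a_pre=0.0, a_post=0.5)
        pl.update_eligibility(s, True, False, 0.01, params)
        assert s.e < 0


class TestRewardEvent:
    def test_rpe_and_q_update(self):
        p = pl.PlasticityParams(alpha_q=0.5, q_init=0.0)
        da = pl.DopamineSystem(params=p)
        _, inc = pl.reward_event(da, 1, 1.0)
        assert inc == pytest.approx(1.0)
        assert da.q[1] == pytest.approx(0.5)

    def test_zero_rpe_leaves_q(self):
        p = pl.PlasticityParams(alpha_q=0.5, q_init=0.0)
        da = pl.DopamineSystem(params=p)
        da.q[1] = 0.8
        _, inc = pl.reward_event(da, 1, 0.8)
        assert inc == 0.0
        assert da.q[1] == pytest.approx(0.8)

    def test_geometric_convergence(self):
        p = pl.PlasticityParams(alpha_q=0.3, q_init=0.0)
        da = pl.DopamineSystem(params=p)
        for k in range(1, 11):
            pl.reward_event(da, 1, 1.0)
            assert da.q[1] == pytest.approx(1 - 0.7**k)

    def test_out_of_range_reward_rejected(self):
        da = pl.DopamineSystem(params=pl.PlasticityParams())
        with pytest.raises(ValueError):
            pl.reward_event(da, 1, 2.0)


class TestFKda:
    def test_dspn_branches(self):
        g, m, e = 0.6, 0.5, 0.8
        assert pl.f_kda(-2 * m, "dSPN", g, m, e) == pytest.approx(-g)
        assert pl.f_kda(m, "dSPN", g, m, e) == pytest.approx(g)
        # continuity at the break point
        assert pl.f_kda(-m, "dSPN", g, m, e) == pytest.approx(-g)

    def test_ispn_branches(self):
        g, m, e = 0.6, 0.5, 0.8
        assert pl.f_kda(3 * m, "iSPN", g, m, e) == pytest.approx(e * g)
        assert pl.f_kda(-m, "iSPN", g, m, e) == pytest.approx(-e * g)
        assert pl.f_kda(m, "iSPN", g, m, e) == pytest.approx(e * g)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            pl.f_kda(0.0, "GPe", 1, 1, 1)


class TestWeightUpdate:
    def test_frozen_at_upper_bound_under_positive_drive(self, params):
        da = pl.DopamineSystem(params=params)
        da.k_da = 1.0
        s = pl.SynapseState(e=1.0, w=0.09)
        pl.update_weight(s, da, "dSPN", 1.0, params, w_min=0.0, w_max=0.09)
        assert s.w == pytest.approx(0.09)

    def test_frozen_at_lower_bound_under_negative_drive(self, params):
        da = pl.DopamineSystem(params=params)
        da.k_da = -0.4
        s = pl.SynapseState(e=1.0, w=0.0)
        pl.update_weight(s, da, "dSPN", 1.0, params, w_min=0.0, w_max=0.09)
        assert s.w == pytest.approx(0.0)

    def test_positive_feedback_moves_pathways_oppositely(self, params):
        """Positive RPE with positive eligibility strengthens dSPN synapses
        and weakens iSPN synapses."""
        da = pl.DopamineSystem(params=params)
        da.k_da = 0.5
        sd = pl.SynapseState(e=0.01, w=0.05)
        si = pl.SynapseState(e=0.01, w=0.05)
        pl.update_weight(sd, da, "dSPN", 1.0, params, 0.0, 0.09)
        pl.update_weight(si, da, "iSPN", 1.0, params, 0.0, 0.09)
        assert sd.w > 0.05
        assert si.w < 0.05


class TestConductance:
    def test_decay_and_jump(self, params):
        s = pl.SynapseState(g=1.0, w=0.5)
        pl.conductance_step(s, False, 2.0)
        assert s.g == pytest.approx(np.exp(-1.0))
        s = pl.SynapseState(g=0.0, w=0.5)
        pl.conductance_step(s, True, 1e-9)
        assert s.g == pytest.approx(0.5)

    def test_two_spike_superposition(self):
        s = pl.SynapseState(g=0.0, w=0.5)
        pl.conductance_step(s, True, 1e-12)
        for _ in range(10):
            pl.conductance_step(s, False, 0.5)  # 5 ms gap
        pl.conductance_step(s, True, 1e-12)
        assert s.g == pytest.approx(0.5 * (1 + np.exp(-5.0 / 2.0)), rel=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.booleans(), st.floats(-1, 1)), min_size=1, max_size=120))
def test_weights_never_leave_bounds(events):
    """Property: for any spike/dopamine event sequence the weight stays in
    [w_min, w_max]."""
    params = pl.PlasticityParams(alpha_w_dspn=5e4, alpha_w_ispn=-5e4)
    da = pl.DopamineSystem(params=params)
    s = pl.SynapseState(w=0.05)
    w_min, w_max = 0.0, 0.09
    for pre, post, k in events:
        pl.update_traces(s, pre, post, 1.0, params)
        pl.update_eligibility(s, pre, post, 1.0, params)
        da.k_da = k
        pl.update_weight(s, da, "dSPN", 1.0, params, w_min, w_max)
        pl.update_weight(s, da, "iSPN", 1.0, params, w_min, w_max)
        assert w_min <= s.w <= w_max


class TestEngine:
    def test_no_dopamine_freezes_weights(self, default_compiled):
        eng = pl.PlasticityEngine(
            default_compiled.initial_weights(), default_compiled.plastic_blocks
        )
        before = eng.snapshot()
        eng.start_trial()
        # learning trial without any reward delivery: K_DA stays 0
        nw.simulate_trials(default_compiled, n_trials=1, seed=3, plasticity=eng, reward_fn=None)
        after = eng.snapshot()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_reward_asymmetry_moves_pathways_oppositely(self, default_compiled):
        """Rewarding channel 1 strengthens its dSPN weights and weakens its
        iSPN weights on average (and conversely for errors on channel 2)."""
        deltas = {"dSPN_ch1": [], "iSPN_ch1": []}
        rng = np.random.default_rng(17)
        for rep in range(4):
            eng = pl.PlasticityEngine(
                default_compiled.initial_weights(), default_compiled.plastic_blocks
            )
            w0 = eng.mean_weights()
            for t in range(4):
                eng.start_trial()
                nw.simulate_trials(
                    default_compiled, n_trials=1, seed=rng.integers(2**31),
                    plasticity=eng, reward_fn=lambda ch: float(ch == 1),
                )
            w1 = eng.mean_weights()
            deltas["dSPN_ch1"].append(w1["dSPN_ch1"] - w0["dSPN_ch1"])
            deltas["iSPN_ch1"].append(w1["iSPN_ch1"] - w0["iSPN_ch1"])
        assert np.mean(deltas["dSPN_ch1"]) > 0
        assert np.mean(deltas["iSPN_ch1"]) < 0

    def test_weights_stay_off_bounds_after_learning(self, default_compiled):
        """The multiplicative rule leaves <5% of weights within 1% of a
        bound after a 15-trial session at default parameters."""
        eng = pl.PlasticityEngine(
            default_compiled.initial_weights(), default_compiled.plastic_blocks
        )
        rng = np.random.default_rng(5)
        for t in range(15):
            eng.start_trial()
            nw.simulate_trials(
                default_compiled, n_trials=1, seed=rng.integers(2**31),
                plasticity=eng, reward_fn=lambda ch: float(ch == 1),
            )
        allw = np.concatenate([v.ravel() for v in eng.weights.values()])
        st0 = eng._state["dSPN_ch1"]
        lo, hi = st0["w_min"], st0["w_max"]
        margin = 0.01 * (hi - lo)
        frac = np.mean((allw < lo + margin) | (allw > hi - margin))
        assert frac < 0.05
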