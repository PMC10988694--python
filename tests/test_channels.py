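import numpy as np
import pytest

from spindlesim import channels as ch


NAV_NAMES = ("nav11", "nav16", "nav17")
TEST_VOLTAGES = (-80.0, -60.0, -45.0, -20.0, 0.0)


class TestHHGates:
    def test_half_activation_at_v_half(self):
        g = ch.HHGate(v_half=-40.0, slope=6.0, tau_base=1.0)
        x, tau = ch.gate_steady_state(g, -40.0)
        assert x == pytest.approx(0.5)
        assert tau > 0

    def test_activation_limit(self):
        g = ch.HHGate(v_half=-40.0, slope=6.0, tau_base=1.0)
        assert ch.gate_steady_state(g, 100.0)[0] == pytest.approx(1.0, abs=1e-6)

    def test_monotone_with_slope_sign(self):
        act = ch.HHGate(v_half=-40.0, slope=6.0, tau_base=1.0)
        inact = ch.HHGate(v_half=-40.0, slope=-6.0, tau_base=1.0)
        vs = np.linspace(-100, 60, 33)
        assert np.all(np.diff(act.steady_state(vs)) > 0)
        assert np.all(np.diff(inact.steady_state(vs)) < 0)

    def test_exact_exponential_update_composes(self):
        """At fixed V the HH update is exact: two half steps = one full step."""
        chan = ch.make_channel("kcnq")
        s0 = np.array([0.2])
        full = ch.step_channel(chan, s0, -40.0, 0.0, 1.0)
        half = ch.step_channel(chan, ch.step_channel(chan, s0, -40.0, 0.0, 0.5),
                               -40.0, 0.0, 0.5)
        np.testing.assert_allclose(full, half, rtol=1e-12)


class TestMarkovSchemes:
    @pytest.mark.parametrize("name", NAV_NAMES)
    @pytest.mark.parametrize("v", TEST_VOLTAGES)
    def test_generator_rows_sum_to_zero(self, name, v):
        q = ch.markov_rate_matrix(ch.make_channel(name).scheme, v)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q - np.diag(np.diag(q))
        assert np.all(off >= 0)

    def test_negative_rate_rejected(self):
        bad = ch.MarkovScheme(
            "bad", ("a", "b"),
            lambda v: np.array([[0.0, -1.0], [1.0, 0.0]]), conducting=(1,),
        )
        with pytest.raises(ch.SchemeError):
            ch.markov_rate_matrix(bad, -60.0)

    def test_two_state_stationary_closed_form(self):
        alpha, beta = 3.0, 7.0
        scheme = ch.MarkovScheme(
            "oc", ("C", "O"),
            lambda v: np.array([[0.0, alpha], [beta, 0.0]]), conducting=(1,),
        )
        p = ch.markov_stationary(scheme, 0.0)
        assert p[1] == pytest.approx(alpha / (alpha + beta), abs=1e-12)

    @pytest.mark.parametrize("name", NAV_NAMES)
    @pytest.mark.parametrize("v", TEST_VOLTAGES)
    def test_time_stepping_converges_to_linear_solve_stationary(self, name, v):
        """Backward-Euler evolution at fixed V reaches the stationary
        distribution computed by a direct linear solve (tolerance 1e-6)."""
        chan = ch.make_channel(name)
        target = ch.markov_stationary(chan.scheme, v)
        p = np.zeros(chan.n_states)
        p[0] = 1.0
        for _ in range(400):
            p = chan.step(p, v, 0.0, 500.0)  # long implicit steps
        assert np.max(np.abs(p - target)) < 1e-6

    @pytest.mark.parametrize("name", NAV_NAMES)
    def test_stationary_is_step_fixed_point(self, name):
        chan = ch.make_channel(name)
        p = chan.init_state(-65.0)
        p2 = chan.step(p, -65.0, 0.0, 0.0125)
        assert np.max(np.abs(p2 - p)) < 1e-9

    @pytest.mark.parametrize("name", NAV_NAMES)
    def test_occupancy_conservation_long_trace(self, name):
        """Occupancy drift stays below 1e-9 over a 10 s trace at dt=0.025 ms
        (fixed-V propagation composed by repeated squaring) and over a
        varying-voltage stepped trace."""
        chan = ch.make_channel(name)
        n = chan.n_states
        q = ch.markov_rate_matrix(chan.scheme, -50.0)
        m = np.linalg.inv(np.eye(n) - 0.025 * q.T)
        # 2**19 steps = 13.1 s at 0.025 ms
        big = np.linalg.matrix_power(m, 2 ** 19)
        p = big @ chan.init_state(-65.0)
        assert abs(p.sum() - 1.0) < 1e-9
        # varying V, explicit stepping (renormalized update)
        p = chan.init_state(-65.0)
        rng = np.random.default_rng(0)
        for v in rng.uniform(-90, 20, size=2000):
            p = chan.step(p, float(v), 0.0, 0.025)
        assert abs(p.sum() - 1.0) < 1e-9 and np.all(p >= 0)


class TestChannelPhenotypes:
    def test_kv3_higher_threshold_than_kv1(self):
        kv1 = ch.make_channel("kv1")
        kv33 = ch.make_channel("kv33")
        v = -45.0
        assert kv1.open_fraction(kv1.init_state(v)) > \
            kv33.open_fraction(kv33.init_state(v))

    def test_kcnq_deactivates_slower_than_kv3_at_minus60(self):
        kcnq = ch.make_channel("kcnq")
        kv33 = ch.make_channel("kv33")
        assert kcnq.gates[0].tau(-60.0) > kv33.gates[0].tau(-60.0)

    @pytest.mark.parametrize("name", NAV_NAMES)
    def test_slow_recovery_slower_than_fast_recovery(self, name):
        """Availability recovers faster after a brief (fast-inactivating)
        pulse than after a long (slow-inactivating) one."""
        chan = ch.make_channel(name)

        def peak_after(pulse_ms, recover_ms):
            state = chan.init_state(-80.0)
            for _ in range(int(pulse_ms / 0.05)):
                state = chan.step(state, 0.0, 0.0, 0.05)
            for _ in range(int(recover_ms / 0.05)):
                state = chan.step(state, -80.0, 0.0, 0.05)
            peak = 0.0
            s = state
            for _ in range(500):
                s = chan.step(s, 0.0, 0.0, 0.01)
                peak = max(peak, chan.open_fraction(s))
            return peak

        assert peak_after(5.0, 20.0) > peak_after(1000.0, 20.0)

    def test_nav16_slow_inactivation_entered_from_open(self):
        """Long depolarization, brief recovery, re-step: the second peak is
        reduced relative to the fully rested response."""
        chan = ch.make_channel("nav16")
        rested = ch.voltage_clamp(chan, -80.0, [(0.0, 5.0)], dt=0.01)[0]["open"].max()
        tr = ch.voltage_clamp(
            chan, -80.0, [(0.0, 500.0), (-80.0, 20.0), (0.0, 5.0)], dt=0.02
        )
        assert tr[2]["open"].max() < 0.85 * rested

    def test_nav16_has_two_slow_inactivated_states(self):
        scheme = ch.make_channel("nav16").scheme
        assert scheme.n_states == 10
        assert "IS1" in scheme.states and "IS2" in scheme.states
        q = ch.markov_rate_matrix(scheme, -20.0)
        i_o = scheme.states.index("O")
        i_if = scheme.states.index("IF")
        assert q[i_o, scheme.states.index("IS1")] > 0   # entered from open
        assert q[i_if, scheme.states.index("IS2")] > 0  # entered from fast-inact

    def test_nav17_is_six_state(self):
        assert ch.make_channel("nav17").n_states == 6

    def test_sk_activation_decays_without_calcium(self):
        sk = ch.make_channel("sk2")
        s = np.array([0.8])
        for _ in range(300):
            s = sk.step(s, -60.0, 0.0, 1.0)
        assert s[0] < 1e-3

    def test_sk_hill_half_activation(self):
        sk = ch.make_channel("sk2")
        assert sk.activation_inf(sk.ca_half) == pytest.approx(0.5)


class TestCurrentAndClamp:
    def test_current_zero_at_reversal(self):
        chan = ch.make_channel("kv33")
        s = chan.init_state(0.0)
        assert ch.channel_current(chan, s, chan.e_rev, 0.01, 100.0) == 0.0

    def test_current_linear_in_area(self):
        chan = ch.make_channel("kv33")
        s = chan.init_state(0.0)
        i1 = ch.channel_current(chan, s, 0.0, 0.01, 100.0)
        i2 = ch.channel_current(chan, s, 0.0, 0.01, 200.0)
        assert i2 == pytest.approx(2.0 * i1)

    def test_zero_open_fraction_zero_current(self):
        chan = ch.make_channel("kv33")
        assert ch.channel_current(chan, np.zeros(1), 0.0, 0.01, 100.0) == 0.0

    def test_clamp_deterministic(self):
        chan = ch.make_channel("nav11")
        a = ch.voltage_clamp(chan, -80.0, [(-10.0, 5.0)], dt=0.02)[0]
        b = ch.voltage_clamp(chan, -80.0, [(-10.0, 5.0)], dt=0.02)[0]
        np.testing.assert_array_equal(a["i"], b["i"])

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            ch.voltage_clamp(ch.make_channel("kv1"), -80.0, [(0.0, 0.0)])
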