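import numpy as np
import pytest

from spindlesim.intrafusal import (
    FiberParams,
    FiberState,
    bag_params,
    chain_params,
    fiber_force,
    initial_state,
    isometric_bound_fraction,
    simulate_fiber,
    step_fiber,
)
from spindlesim.stimuli import RampSpec, make_ramp_hold_release


def flat_state(p: FiberParams, a_on=0.0) -> FiberState:
    return FiberState(bound=np.zeros(p.n_bins), a_on=a_on, hsl=p.hsl0)


class TestStepFiber:
    def test_all_zero_fixed_point(self):
        p = FiberParams(activation=0.0)
        st = flat_state(p)
        out = step_fiber(st, p, 0.0, 1e-4)
        assert out.a_on == 0.0
        assert np.all(out.bound == 0.0)

    def test_constant_rate_steady_state_matches_two_state_analytics(self):
        # strain-independent detachment (x_d -> inf), thin filament pinned at 1
        p = FiberParams(f0=30.0, g0=10.0, x_d=np.inf, k_off=0.0, activation=1.0,
                        overlap_gain=0.0)
        st = FiberState(bound=np.zeros(p.n_bins), a_on=1.0, hsl=p.hsl0)
        dt = 1e-4
        for _ in range(30000):
            st = step_fiber(st, p, 0.0, dt)
        assert st.bound_fraction(p) == pytest.approx(
            isometric_bound_fraction(30.0, 10.0), abs=1e-3
        )

    def test_sliding_shifts_bound_density(self):
        # pure shift: no kinetics (f0 = 0, detachment off)
        p = FiberParams(f0=0.0, g0=0.0, x_d=np.inf, activation=0.0)
        x = p.x
        bound = np.exp(-0.5 * ((x + 1.0) / 1.5) ** 2)
        st = FiberState(bound=bound.copy(), a_on=1.0, hsl=p.hsl0)
        out = step_fiber(st, p, 2.0, 1e-4)
        mean0 = np.sum(x * bound) / bound.sum()
        mean1 = np.sum(x * out.bound) / out.bound.sum()
        assert mean1 - mean0 == pytest.approx(2.0, abs=0.05)

    def test_rejects_bad_inputs(self):
        p = FiberParams()
        with pytest.raises(ValueError):
            step_fiber(flat_state(p), p, 0.0, 0.0)
        with pytest.raises(ValueError):
            step_fiber(flat_state(p), p, np.nan, 1e-4)


class TestIsometricOracle:
    @pytest.mark.parametrize("f,g,expect", [(1.0, 1.0, 0.5), (3.0, 1.0, 0.75)])
    def test_closed_form(self, f, g, expect):
        assert isometric_bound_fraction(f, g) == expect

    def test_zero_rates_undefined(self):
        with pytest.raises(ZeroDivisionError):
            isometric_bound_fraction(0.0, 0.0)


@pytest.fixture(scope="module")
def short_ramp():
    return make_ramp_hold_release(
        RampSpec(baseline_s=0.1, amplitude_mm=3.0, hold_s=0.4, post_s=0.1)
    )


class TestSimulateFiber:
    def test_zero_stimulus_isometric(self):
        spec = RampSpec(baseline_s=0.05, amplitude_mm=0.0, hold_s=0.0, post_s=0.1)
        tr = simulate_fiber(bag_params(), make_ramp_hold_release(spec))
        assert np.ptp(tr.force) < 1e-3 * abs(tr.force[0])
        assert np.max(np.abs(tr.yank[2:-2])) < 1e-2 * abs(tr.force[0])

    def test_force_linear_in_crossbridge_number(self, short_ramp):
        tr1 = simulate_fiber(bag_params(), short_ramp)
        tr2 = simulate_fiber(bag_params(n_xb=2.0), short_ramp)
        np.testing.assert_allclose(tr2.force, 2.0 * tr1.force, rtol=1e-9)

    def test_chain_relaxes_faster_than_bag(self, short_ramp):
        """The fast (chain) fibre approaches its post-ramp steady force
        sooner than the slow (bag) fibre under the same ramp."""
        spec = RampSpec(baseline_s=0.1, amplitude_mm=3.0, hold_s=0.4, post_s=0.1)
        ramp_off = spec.phase_times()["ramp_off"]

        def settle_time(tr):
            m = tr.t >= ramp_off
            t, f = tr.t[m], tr.force[m]
            f_end = f[-1]
            dev = np.abs(f - f_end) / abs(np.ptp(tr.force))
            below = dev < 0.10
            # first time after which the force stays within 10% of steady
            idx = len(below) - np.argmin(below[::-1]) if not below.all() else 0
            return t[min(idx, len(t) - 1)] - ramp_off

        t_bag = settle_time(simulate_fiber(bag_params(), short_ramp))
        t_chain = settle_time(simulate_fiber(chain_params(), short_ramp))
        assert t_chain < t_bag

    def test_probability_bounds_throughout(self, short_ramp):
        p = bag_params()
        st = initial_state(p)
        dhsl = np.diff(short_ramp.length) * p.length_gain
        for d in dhsl[: 3000]:
            st = step_fiber(st, p, float(d), short_ramp.dt)
            nb = st.bound_fraction(p)
            assert -1e-12 <= nb <= st.a_on + 1e-9 <= 1.0 + 1e-9

    def test_ramp_force_exceeds_hold_plateau(self, short_ramp):
        """History dependence: the dynamic (ramp) force transient overshoots
        the static plateau — the mechanical origin of dynamic firing."""
        spec = RampSpec(baseline_s=0.1, amplitude_mm=3.0, hold_s=0.4, post_s=0.1)
        ph = spec.phase_times()
        tr = simulate_fiber(bag_params(), short_ramp)
        ramp_mask = (tr.t >= ph["ramp_on"]) & (tr.t <= ph["ramp_off"] + 0.01)
        late_hold = (tr.t >= ph["release_on"] - 0.1) & (tr.t <= ph["release_on"])
        assert tr.force[ramp_mask].max() > tr.force[late_hold].mean() * 1.05

    def test_grid_refinement_stability(self):
        """Halving strain-bin width and dt changes the force trace by <1%."""
        spec = RampSpec(baseline_s=0.05, amplitude_mm=2.0, hold_s=0.15,
                        post_s=0.05, dt_s=2e-4)
        stim = make_ramp_hold_release(spec)
        spec_fine = RampSpec(baseline_s=0.05, amplitude_mm=2.0, hold_s=0.15,
                             post_s=0.05, dt_s=1e-4)
        stim_fine = make_ramp_hold_release(spec_fine)
        tr = simulate_fiber(bag_params(), stim)
        tr_fine = simulate_fiber(bag_params(n_bins=321), stim_fine)
        f_interp = np.interp(stim.t, stim_fine.t, tr_fine.force)
        err = np.max(np.abs(tr.force - f_interp)) / np.max(np.abs(f_interp))
        assert err < 0.01
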