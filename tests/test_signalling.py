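"""Interneuron signalling kinetics: fixed points, sigmoids, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nvcgaba import (InvalidProtocolError, SignallingState,
                     gaba_degradation_rate, gaba_rhs, gaba_t_activity,
                     glu_rhs, glutamate_release, heaviside_input, no_rhs,
                     npy_rhs)


def state(gaba=0.0, npy=0.0, glu=0.0, no_n=0.02047):
    return SignallingState(gaba=gaba, npy=npy, glu=glu, no_n=no_n)


@pytest.mark.parametrize("t, t0, dt, expected", [
    (1500.0, 1000.0, 2000.0, 1.0),   # inside the window
    (999.0, 1000.0, 2000.0, 0.0),    # before onset
    (3001.0, 1000.0, 2000.0, 0.0),   # after offset
    (1000.0, 1000.0, 2000.0, 0.0),   # boundaries are exclusive
    (3000.0, 1000.0, 2000.0, 0.0),
])
def test_heaviside_window(t, t0, dt, expected):
    assert heaviside_input(t, t0, dt) == expected


def test_heaviside_rejects_nonpositive_duration():
    with pytest.raises(InvalidProtocolError):
        heaviside_input(0.0, 0.0, 0.0)


class TestGabaTActivity:
    def test_midpoint_is_mean_of_bounds(self, sig):
        assert gaba_t_activity(sig.gt_midpoint, sig) == pytest.approx(1.5)

    def test_saturating_no_reaches_minimum(self, sig):
        assert gaba_t_activity(1e6, sig) == pytest.approx(sig.gt_min)

    def test_value_at_zero_no(self, sig):
        # direct evaluation of the sigmoid: tanh(-0.06/0.02128)
        expected = 0.5 * (3.0 + np.tanh(0.06 / 0.02128))
        assert gaba_t_activity(0.0, sig) == pytest.approx(expected, rel=1e-12)
        assert gaba_t_activity(0.0, sig) == pytest.approx(1.9964, abs=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(no=st.floats(min_value=0.0, max_value=1.0))
    def test_bounded_and_monotone(self, sig, no):
        a = gaba_t_activity(no, sig)
        assert sig.gt_min <= a <= sig.gt_max
        if no < 0.15:  # away from float saturation of the tanh
            assert sig.gt_min < a < sig.gt_max
        assert gaba_t_activity(no + 0.01, sig) <= a


@pytest.mark.parametrize("gt_act, beta, expected", [
    (1.0, 2.2e-3, 2.2e-3),
    (2.0, 2.2e-3, 4.4e-3),
    (0.5, 1.0, 0.5),
])
def test_gaba_degradation_scales_with_activity(gt_act, beta, expected, sig):
    import dataclasses
    p = dataclasses.replace(sig, beta_gaba=beta)
    assert gaba_degradation_rate(gt_act, p) == pytest.approx(expected)


class TestStateEquations:
    def test_gaba_baseline_is_fixed_point(self, sig):
        assert gaba_rhs(state(gaba=sig.gaba_base), 0.0, sig) == 0.0

    def test_npy_baseline_is_fixed_point(self, sig):
        assert npy_rhs(state(npy=sig.npy_base), 0.0, sig) == 0.0

    def test_no_baseline_is_fixed_point(self, sig):
        assert no_rhs(state(no_n=sig.no_rest), 0.0, False, sig) == pytest.approx(0.0)

    def test_gaba_steady_elevation_closed_form(self, sig):
        # sustained input, GABA-T pinned at its minimum: elevation alpha/beta
        ss = sig.gaba_base + sig.alpha_gaba / (sig.beta_gaba * sig.gt_min)
        assert gaba_rhs(state(gaba=ss), 1.0, sig, gt_act=sig.gt_min) == pytest.approx(0.0, abs=1e-15)
        assert ss == pytest.approx(0.7273, abs=1e-4)

    def test_gaba_elevation_halves_when_activity_doubles(self, sig):
        lo = sig.alpha_gaba / (sig.beta_gaba * sig.gt_min)
        hi = sig.alpha_gaba / (sig.beta_gaba * sig.gt_max)
        assert 100.0 * (1.0 - hi / lo) == pytest.approx(
            100.0 * (1.0 - sig.gt_min / sig.gt_max))

    def test_npy_steady_elevation_and_decay(self, sig):
        ss = sig.npy_base + sig.alpha_npy / sig.beta_npy
        assert npy_rhs(state(npy=ss), 1.0, sig) == pytest.approx(0.0, abs=1e-15)
        assert ss == pytest.approx(1.909, abs=1e-3)
        # post-pulse decay: exponential with time constant 1/beta_npy
        sol = solve_ivp(lambda t, y: [npy_rhs(state(npy=y[0]), 0.0, sig)],
                        (0.0, 454.5454545), [ss], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(ss * np.exp(-1.0), rel=1e-6)

    def test_no_lname_drives_to_zero(self, sig):
        sol = solve_ivp(
            lambda t, y: [no_rhs(state(no_n=y[0]), 1.0, True, sig)],
            (0.0, 20000.0), [sig.no_rest], rtol=1e-10, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(0.0, abs=1e-8)

    def test_no_sustained_input_steady_state(self, sig):
        ss = sig.no_rest + sig.no_alpha / sig.no_beta
        assert no_rhs(state(no_n=ss), 1.0, False, sig) == pytest.approx(0.0, abs=1e-15)


class TestGlutamate:
    def test_release_half_max_at_switch(self, sig):
        assert glutamate_release(sig.ke_switch, sig) == pytest.approx(sig.glu_max / 2)

    def test_release_saturates(self, sig):
        assert glutamate_release(1e3, sig) == pytest.approx(sig.glu_max)

    def test_release_negligible_at_rest(self, sig):
        assert glutamate_release(0.0, sig) < 1e-20 * sig.glu_max

    def test_rest_is_fixed_point_with_sources_off(self, sig):
        assert glu_rhs(state(), 0.0, sig) == pytest.approx(0.0, abs=1e-20)

    def test_gaba_source_scales_with_activity(self, sig):
        g1 = glu_rhs(state(gaba=1.0), 0.0, sig, gt_act=1.0)
        g2 = glu_rhs(state(gaba=1.0), 0.0, sig, gt_act=2.0)
        assert g2 == pytest.approx(2.0 * g1)

    def test_sustained_release_steady_state(self, sig):
        f = glutamate_release(8.0, sig)
        ss = f / sig.beta_glu
        assert glu_rhs(state(glu=ss), 8.0, sig) == pytest.approx(0.0, abs=1e-15)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(t0=st.floats(0.0, 5000.0), dur=st.floats(100.0, 5000.0),
       seed_no=st.floats(0.0, 0.5))
def test_concentrations_stay_nonnegative(sig, t0, dur, seed_no):
    """Random rectangular protocols never drive any species negative."""
    def rhs(t, y):
        s = SignallingState(*y)
        i = heaviside_input(t, t0, dur)
        return [gaba_rhs(s, i, sig), npy_rhs(s, i, sig),
                glu_rhs(s, 3.0, sig), no_rhs(s, i, False, sig)]

    sol = solve_ivp(rhs, (0.0, t0 + dur + 3000.0),
                    [sig.gaba_base, sig.npy_base, 0.0, seed_no],
                    rtol=1e-8, atol=1e-12, max_step=dur / 4)
    assert np.all(sol.y >= -1e-9)
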