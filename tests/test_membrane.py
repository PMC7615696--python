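"""Channel fluxes and the electro-vascular surrogate: algebra and sign chains."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nvcgaba import (SignallingState, VascularState, baseline_vascular_state,
                     gaba_conductance, gaba_flux, surrogate_rhs,
                     vocc_conductance, vocc_flux)
from nvcgaba.membrane import radius_target


def sstate(gaba=0.0, npy=0.0, glu=0.0, no_n=0.02047):
    return SignallingState(gaba=gaba, npy=npy, glu=glu, no_n=no_n)


class TestGabaChannel:
    def test_conductance_midpoint(self, chan):
        assert gaba_conductance(chan.g_mid, chan) == pytest.approx(chan.g_gaba_max / 2)

    def test_conductance_near_zero_at_rest(self, chan):
        # (1 + tanh(-0.5/0.15))/2 of the maximum
        frac = 0.5 * (1 + math.tanh(-chan.g_mid / chan.g_slope))
        assert gaba_conductance(0.0, chan) == pytest.approx(
            chan.g_gaba_max * frac, rel=1e-12)
        assert gaba_conductance(0.0, chan) < 2e-3 * chan.g_gaba_max

    def test_max_conductance_is_fraction_of_cl_leak(self, chan):
        assert chan.g_gaba_max == pytest.approx(0.3 * chan.g_cl_i)
        assert chan.g_gaba_max == pytest.approx(4.02e-7)

    def test_flux_zero_at_reversal(self, chan):
        for gaba in (0.0, 0.5, 1.0, 2.0):
            assert gaba_flux(chan.e_gaba, gaba, chan) == 0.0

    def test_flux_direct_product(self, chan):
        # fully open channel at -25 mV: G * 50 mV
        high = 5.0  # saturates the conductance sigmoid
        assert gaba_flux(-25.0, high, chan) == pytest.approx(
            chan.g_gaba_max * 50.0, rel=1e-6)

    def test_flux_sign_change_at_reversal(self, chan):
        assert gaba_flux(chan.e_gaba - 1.0, 1.0, chan) < 0
        assert gaba_flux(chan.e_gaba + 1.0, 1.0, chan) > 0


class TestVocc:
    def test_endpoint_convention_hits_both_endpoints(self, chan):
        assert vocc_conductance(0.0, chan) == pytest.approx(chan.g_ca_i, rel=1e-14)
        assert vocc_conductance(1.0, chan) == pytest.approx(
            (1 + chan.n_inc) * chan.g_ca_i, rel=1e-14)

    def test_midpoint_between_endpoints(self, chan):
        g = vocc_conductance(chan.n_mid, chan)
        assert chan.g_ca_i < g < (1 + chan.n_inc) * chan.g_ca_i

    def test_literal_form_misses_endpoints(self, chan):
        lit = dataclasses.replace(chan, vocc_sigmoid="literal")
        g0 = vocc_conductance(0.0, lit)
        expected = chan.g_ca_i * (1 + 0.5 * chan.n_inc * math.tanh(
            -chan.n_mid / chan.n_slope))
        assert g0 == pytest.approx(expected, rel=1e-12)
        assert g0 != pytest.approx(chan.g_ca_i, rel=1e-6)

    def test_activation_half_at_half_point(self, chan):
        f = vocc_flux(chan.v_ca2, 0.0, chan)
        assert f == pytest.approx(
            0.5 * chan.g_ca_i * (chan.v_ca2 - chan.v_ca1), rel=1e-12)

    def test_flux_zero_at_reversal(self, chan):
        assert vocc_flux(chan.v_ca1, 0.0, chan) == 0.0

    def test_flux_direct_evaluation(self, chan):
        f = vocc_flux(-60.0, 0.0, chan)
        assert f == pytest.approx(
            chan.g_ca_i * (-160.0) / (1 + math.exp(36.0 / 8.5)), rel=1e-12)

    def test_flux_inward_below_reversal(self, chan):
        for v in (-80.0, -45.0, 0.0, 99.0):
            assert vocc_flux(v, 0.5, chan) <= 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(x=st.floats(0.0, 2.0))
def test_conductances_monotone(chan, x):
    assert gaba_conductance(x + 0.01, chan) >= gaba_conductance(x, chan)
    assert vocc_conductance(x + 0.01, chan) >= vocc_conductance(x, chan)


# ---------------------------------------------------------------------------
# surrogate dynamics
# ---------------------------------------------------------------------------


def _rhs_vec(y, s, i_ke, chan, surr, j_ref):
    v = VascularState(v_k=y[0], v_i=y[1], ca_i=y[2], radius=y[3],
                      k_e=y[4], k_p=y[5])
    return np.array(surrogate_rhs(v, s, i_ke, chan, surr, j_ref))


def _steady(s, chan, surr, t_end=60000.0):
    base = baseline_vascular_state(chan, surr)
    j_ref = vocc_flux(base.v_i, 0.0, chan)
    y0 = [base.v_k, base.v_i, base.ca_i, base.radius, base.k_e, base.k_p]
    sol = solve_ivp(lambda t, y: _rhs_vec(y, s, 0.0, chan, surr, j_ref),
                    (0.0, t_end), y0, rtol=1e-9, atol=1e-11)
    return sol.y[:, -1]


def test_baseline_is_fixed_point(chan, surr):
    base = baseline_vascular_state(chan, surr)
    j_ref = vocc_flux(base.v_i, 0.0, chan)
    dy = _rhs_vec([base.v_k, base.v_i, base.ca_i, base.radius,
                   base.k_e, base.k_p], sstate(), 0.0, chan, surr, j_ref)
    assert np.max(np.abs(dy)) < 1e-12


def test_perturbed_state_returns_to_baseline(chan, surr):
    base = baseline_vascular_state(chan, surr)
    j_ref = vocc_flux(base.v_i, 0.0, chan)
    y0 = [base.v_k + 5, base.v_i - 5, 1.2, 0.9, base.k_e + 2, base.k_p + 1]
    sol = solve_ivp(lambda t, y: _rhs_vec(y, sstate(), 0.0, chan, surr, j_ref),
                    (0.0, 10000.0), y0, rtol=1e-9, atol=1e-11)
    expected = [base.v_k, base.v_i, 1.0, 1.0, base.k_e, base.k_p]
    assert np.allclose(sol.y[:, -1], expected, atol=1e-4)


def test_potassium_dilation_sign_chain(chan, surr):
    """Raising perivascular K+ hyperpolarises the SMC, lowers Ca2+, dilates."""
    base = baseline_vascular_state(chan, surr)
    j_ref = vocc_flux(base.v_i, 0.0, chan)
    v = VascularState(v_k=base.v_k, v_i=base.v_i, ca_i=1.0, radius=1.0,
                      k_e=base.k_e, k_p=base.k_p + 4.0)
    dv = surrogate_rhs(v, sstate(), 0.0, chan, surr, j_ref)
    assert dv[1] < 0  # dv_i: hyperpolarising
    hyper = VascularState(v_k=base.v_k, v_i=base.v_i - 10.0, ca_i=1.0,
                          radius=1.0, k_e=base.k_e, k_p=base.k_p)
    dca = surrogate_rhs(hyper, sstate(), 0.0, chan, surr, j_ref)[2]
    assert dca < 0  # lower VOCC activation lowers Ca2+
    assert radius_target(0.8, surr) > 1.0  # lower Ca2+ dilates


def test_gaba_dilates_npy_constricts(chan, surr):
    """Steady radius > 1 with GABA elevated; < 1 with NPY elevated."""
    y_gaba = _steady(sstate(gaba=0.9), chan, surr)
    assert y_gaba[3] > 1.0
    y_npy = _steady(sstate(npy=1.5), chan, surr)
    assert y_npy[3] < 1.0
    assert y_npy[2] > 1.0  # NPY raised SMC Ca2+
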