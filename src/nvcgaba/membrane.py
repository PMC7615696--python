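"""Channel fluxes and the reduced electro-vascular surrogate.

Two channel families couple the interneuron signalling to the vessel wall:

* GABA-gated Cl- channels, one population on the astrocyte and one on the
  smooth muscle cell (SMC), with conductance a saturating sigmoid of
  nondimensional GABA and reversal potential E_GABA = -75 mV. Elevated GABA
  pulls the SMC toward E_GABA (hyperpolarisation), closing the
  voltage-operated Ca2+ channel and dilating the arteriole.
* The voltage-operated Ca2+ channel (VOCC) on the SMC, whose conductance is
  increased by NPY (up to +5% at the nominal maximal NPY), raising Ca2+
  influx and constricting the arteriole.

Instead of the full multicellular electrophysiology, the path from
perivascular K+ and the channel fluxes down to the arteriolar radius is a
six-state first-order surrogate (K_e, K_p, v_k, v_i, Ca_i, radius) that
preserves the sign chains of the mechanism: K+ release hyperpolarises the
SMC through a KIR-like shift and dilates; NPY opens the VOCC and
constricts; GABA hyperpolarises and dilates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ChannelParams, SurrogateParams
from .signalling import SignallingState

__all__ = [
    "VascularState",
    "gaba_conductance",
    "gaba_flux",
    "vocc_conductance",
    "vocc_flux",
    "baseline_vascular_state",
    "surrogate_rhs",
]


@dataclass
class VascularState:
    """Electro-vascular surrogate state.

    v_k / v_i are the astrocyte / SMC membrane potentials (mV), ca_i the
    SMC cytosolic Ca2+ relative to baseline (1 = rest), radius the
    arteriolar radius relative to baseline, k_e / k_p extracellular and
    perivascular K+ (mM).
    """

    v_k: float
    v_i: float
    ca_i: float
    radius: float
    k_e: float
    k_p: float


def gaba_conductance(gaba_n: float, p: ChannelParams) -> float:
    """GABA-gated Cl- conductance (uM mV^-1 ms^-1).

    Saturating sigmoid of nondimensional GABA: essentially zero at rest and
    approaching the maximal conductance ``g_gaba_max`` at stimulated GABA
    levels.
    """
    return 0.5 * p.g_gaba_max * (1.0 + np.tanh((gaba_n - p.g_mid) / p.g_slope))


def gaba_flux(v: float, gaba_n: float, p: ChannelParams) -> float:
    """Cl- flux through the GABA-gated channel at membrane potential ``v``.

    Ohmic form ``g_gaba(gaba_n) * (v - e_gaba)``; identical on the
    astrocyte (v_k) and the SMC (v_i). Zero at the reversal potential.
    """
    return gaba_conductance(gaba_n, p) * (v - p.e_gaba)


def _sigma(x: float, p: ChannelParams) -> float:
    return 0.5 * (1.0 + math.tanh((x - p.n_mid) / p.n_slope))


def vocc_conductance(npy_n: float, p: ChannelParams) -> float:
    """NPY-modulated VOCC conductance (uM mV^-1 ms^-1).

    In the default ``endpoint`` convention the NPY sigmoid is affinely
    rescaled so that the conductance is exactly the base value ``g_ca_i``
    at NPY = 0 and exactly ``(1 + n_inc) * g_ca_i`` at NPY = 1. The
    ``literal`` convention keeps the raw half-amplitude tanh form, which
    misses both endpoints slightly; it is retained for comparison.
    """
    if p.vocc_sigmoid == "literal":
        s = 0.5 * p.n_inc * math.tanh((npy_n - p.n_mid) / p.n_slope)
        return p.g_ca_i * (1.0 + s)
    s0, s1 = _sigma(0.0, p), _sigma(1.0, p)
    s = (_sigma(npy_n, p) - s0) / (s1 - s0)
    return p.g_ca_i * (1.0 + p.n_inc * s)


def vocc_flux(v_i: float, npy_n: float, p: ChannelParams) -> float:
    """Ca2+ flux through the VOCC (uM ms^-1), negative = inward.

    ``g_vocc * (v_i - v_ca1) / (1 + exp(-(v_i - v_ca2)/r_ca))``: the
    activation factor is half at the half-point v_ca2 and the driving force
    vanishes at the reversal potential v_ca1, so the flux is inward
    (negative) for physiological potentials.
    """
    activation = 1.0 / (1.0 + math.exp(-(v_i - p.v_ca2) / p.r_ca))
    return vocc_conductance(npy_n, p) * (v_i - p.v_ca1) * activation


# --------------------------------------------------------------------------
# reduced electro-vascular surrogate
# --------------------------------------------------------------------------


def _v_fixed_point(v_target: float, tau: float, g: float, e_rev: float,
                   w: float) -> float:
    # steady state of dv/dt = (v_target - v)/tau - w*g*(v - e_rev)
    c = tau * w * g
    return (v_target + c * e_rev) / (1.0 + c)


def baseline_vascular_state(cp: ChannelParams, sp: SurrogateParams,
                            gaba_base: float = 0.0) -> VascularState:
    """Analytic resting fixed point of the surrogate (all inputs off)."""
    g0 = gaba_conductance(gaba_base, cp)
    v_k = _v_fixed_point(sp.v_k_rest, sp.tau_vk, g0, cp.e_gaba, sp.w_gaba)
    v_i = _v_fixed_point(sp.v_i_rest, sp.tau_vi, g0, cp.e_gaba, sp.w_gaba)
    return VascularState(v_k=v_k, v_i=v_i, ca_i=1.0, radius=1.0,
                         k_e=sp.k_e_base, k_p=sp.k_e_base)


def radius_target(ca_i: float, sp: SurrogateParams) -> float:
    """Monotone decreasing saturating radius response to cytosolic Ca2+."""
    return 1.0 + sp.r_amp * math.tanh((1.0 - ca_i) / sp.ca_scale)


def surrogate_rhs(vstate: VascularState, sstate: SignallingState,
                  i_ke: float, cp: ChannelParams, sp: SurrogateParams,
                  j_vocc_ref: float) -> tuple[float, float, float, float, float, float]:
    """Time derivatives of the six surrogate states.

    Parameters
    ----------
    i_ke:
        K+ stimulation indicator (1 during whisker stimulation).
    j_vocc_ref:
        VOCC flux at the resting fixed point, used to normalise the Ca2+
        production so the baseline is exactly ca_i = 1.

    Returns derivatives of (v_k, v_i, ca_i, radius, k_e, k_p) in that order.
    """
    # extracellular K+ with stimulation-gated source; perivascular K+ lags it
    dk_e = (sp.k_e_base - vstate.k_e) / sp.tau_ke + sp.k_amp * i_ke
    dk_p = (vstate.k_e - vstate.k_p) / sp.tau_kp

    # astrocyte: depolarised by K+ uptake, nudged toward e_gaba by Cl- flux
    vk_target = sp.v_k_rest + sp.k_dep_amp * math.tanh(
        (vstate.k_e - sp.k_e_base) / sp.k_dep_scale)
    dv_k = ((vk_target - vstate.v_k) / sp.tau_vk
            - sp.w_gaba * gaba_flux(vstate.v_k, sstate.gaba, cp))

    # SMC: KIR-like hyperpolarisation by perivascular K+, GABA Cl- flux pulls
    # toward e_gaba; optional 20-HETE-like depolarising term (off by default)
    vi_target = (sp.v_i_rest
                 - sp.kir_amp * math.tanh((vstate.k_p - sp.k_e_base) / sp.kir_scale)
                 + sp.hete_gain * math.tanh(sstate.glu))
    dv_i = ((vi_target - vstate.v_i) / sp.tau_vi
            - sp.w_gaba * gaba_flux(vstate.v_i, sstate.gaba, cp))

    # SMC Ca2+: production proportional to the inward VOCC flux, normalised
    # so the resting flux maps to the baseline level 1
    ca_inf = vocc_flux(vstate.v_i, sstate.npy, cp) / j_vocc_ref
    dca = (ca_inf - vstate.ca_i) / sp.tau_ca

    # radius relaxes to its Ca2+-determined target
    dr = (radius_target(vstate.ca_i, sp) - vstate.radius) / sp.tau_r

    return dv_k, dv_i, dca, dr, dk_e, dk_p
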