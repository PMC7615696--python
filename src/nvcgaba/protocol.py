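"""Experimental conditions and the coupled simulation driver.

Four conditions are modelled: whisker or optogenetic stimulation, each with
or without the NOS blocker L-NAME. Stimulus routing follows the pathway
picture: whisker (somatosensory) stimulation releases K+ into the
extracellular space and drives neuronal NO; optogenetic stimulation of
nNOS-expressing interneurons releases GABA, NPY (with a pulse half the
width of GABA's) and NO. L-NAME is a pure switch in the NO equation — no
other parameter changes between drug and no-drug runs.

A run equilibrates the full 13-state system to its resting fixed point,
then integrates piecewise-smoothly across the stimulus breakpoints and
returns fractional hemoglobin changes on a uniform output grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import hemodynamics as hemo
from . import membrane, signalling
from .errors import ConfigurationError, IntegrationFailureError, InvalidProtocolError
from .params import Config

__all__ = ["StimulusProtocol", "CoupledModel", "route_inputs", "equilibrate",
           "run_condition", "CONDITIONS"]

CONDITIONS = ("whisker", "optogenetic")

# state vector layout
_IDX = {name: i for i, name in enumerate(
    ["gaba", "npy", "glu", "no_n",            # signalling
     "k_e", "k_p", "v_k", "v_i", "ca_i", "radius",  # vascular surrogate
     "volume", "dhb",                          # balloon
     "activity"])}                             # metabolic activity lag
N_STATES = len(_IDX)


@dataclass(frozen=True)
class StimulusProtocol:
    """One experimental condition.

    kind: 'whisker' (somatosensory) or 'optogenetic' (nNOS interneurons).
    t0/duration in ms; npy_width_factor scales the NPY pulse relative to
    the GABA pulse (default half); lname switches off all NO production.
    """

    kind: str
    t0: float = 2000.0
    duration: float = 2000.0
    lname: bool = False
    npy_width_factor: float = 0.5
    baseline_duration: float = 60000.0

    def __post_init__(self):
        if self.kind not in CONDITIONS:
            raise InvalidProtocolError(
                f"unknown stimulus kind {self.kind!r}; expected one of {CONDITIONS}")
        if self.duration <= 0:
            raise InvalidProtocolError("stimulus duration must be > 0")
        if not 0 < self.npy_width_factor <= 1:
            raise InvalidProtocolError("npy_width_factor must lie in (0, 1]")
        if self.t0 < 0 or self.baseline_duration <= 0:
            raise InvalidProtocolError("t0 must be >= 0 and baseline_duration > 0")


def route_inputs(p: StimulusProtocol, t: float) -> tuple[float, float, float, float]:
    """Per-species input indicators ``(i_ke, i_gaba, i_npy, i_no)`` at time t.

    Whisker stimulation drives extracellular K+ and NO; optogenetic
    stimulation drives GABA, NPY (half-width pulse) and NO. The L-NAME
    switch acts inside the NO kinetics, not here.
    """
    main = signalling.heaviside_input(t, p.t0, p.duration)
    if p.kind == "whisker":
        return main, 0.0, 0.0, main
    npy = signalling.heaviside_input(t, p.t0, p.duration * p.npy_width_factor)
    return 0.0, main, npy, main


class CoupledModel:
    """The full interneuron–vessel–balloon system for one configuration."""

    def __init__(self, config: Config | None = None):
        self.config = config or Config()
        cp, sp = self.config.channels, self.config.surrogate
        sig = self.config.signalling
        self._vbase = membrane.baseline_vascular_state(cp, sp, sig.gaba_base)
        # resting VOCC flux normalises the Ca2+ production term
        self._j_vocc_ref = membrane.vocc_flux(self._vbase.v_i, sig.npy_base, cp)
        if self._j_vocc_ref == 0:
            raise ConfigurationError("resting VOCC flux vanished; cannot normalise Ca2+")

    # -- state helpers ----------------------------------------------------

    def baseline_guess(self, lname: bool = False) -> np.ndarray:
        """Analytic resting state used to start equilibration."""
        sig = self.config.signalling
        y = np.empty(N_STATES)
        y[_IDX["gaba"]] = sig.gaba_base
        y[_IDX["npy"]] = sig.npy_base
        glu_src = (signalling.glutamate_release(self.config.surrogate.k_e_base, sig)
                   + signalling.gaba_degradation_rate(
                       signalling.gaba_t_activity(
                           0.0 if lname else sig.no_rest, sig), sig) * sig.gaba_base)
        y[_IDX["glu"]] = glu_src / sig.beta_glu
        y[_IDX["no_n"]] = 0.0 if lname else sig.no_rest
        y[_IDX["k_e"]] = self._vbase.k_e
        y[_IDX["k_p"]] = self._vbase.k_p
        y[_IDX["v_k"]] = self._vbase.v_k
        y[_IDX["v_i"]] = self._vbase.v_i
        y[_IDX["ca_i"]] = 1.0
        y[_IDX["radius"]] = 1.0
        y[_IDX["volume"]] = 1.0
        y[_IDX["dhb"]] = 1.0
        y[_IDX["activity"]] = 0.0
        return y

    def unpack(self, y: np.ndarray) -> dict[str, float]:
        return {name: float(y[i]) for name, i in _IDX.items()}

    # -- dynamics ---------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, inputs: tuple[float, float, float, float],
            lname: bool, cmro_gain: float) -> np.ndarray:
        """Full coupled right-hand side with frozen input indicators."""
        i_ke, i_gaba, i_npy, i_no = inputs
        cfg = self.config
        sig = cfg.signalling
        sstate = signalling.SignallingState(
            gaba=y[_IDX["gaba"]], npy=y[_IDX["npy"]],
            glu=y[_IDX["glu"]], no_n=max(y[_IDX["no_n"]], 0.0))
        vstate = membrane.VascularState(
            v_k=y[_IDX["v_k"]], v_i=y[_IDX["v_i"]], ca_i=y[_IDX["ca_i"]],
            radius=y[_IDX["radius"]], k_e=y[_IDX["k_e"]], k_p=y[_IDX["k_p"]])

        gt_act = signalling.gaba_t_activity(sstate.no_n, sig)
        dy = np.empty(N_STATES)
        dy[_IDX["gaba"]] = signalling.gaba_rhs(sstate, i_gaba, sig, gt_act)
        dy[_IDX["npy"]] = signalling.npy_rhs(sstate, i_npy, sig)
        dy[_IDX["glu"]] = signalling.glu_rhs(sstate, vstate.k_e, sig, gt_act)
        dy[_IDX["no_n"]] = signalling.no_rhs(sstate, i_no, lname, sig)

        dv_k, dv_i, dca, dr, dk_e, dk_p = membrane.surrogate_rhs(
            vstate, sstate, i_ke, cfg.channels, cfg.surrogate, self._j_vocc_ref)
        dy[_IDX["v_k"]] = dv_k
        dy[_IDX["v_i"]] = dv_i
        dy[_IDX["ca_i"]] = dca
        dy[_IDX["radius"]] = dr
        dy[_IDX["k_e"]] = dk_e
        dy[_IDX["k_p"]] = dk_p

        f_in = hemo.cbf_from_radius(vstate.radius)
        bstate = hemo.BalloonState(volume=y[_IDX["volume"]], dhb=y[_IDX["dhb"]])
        dv, dq = hemo.balloon_rhs(bstate, f_in, cfg.balloon)
        dy[_IDX["volume"]] = dv
        dy[_IDX["dhb"]] = dq

        i_main = max(i_ke, i_gaba)
        dy[_IDX["activity"]] = (i_main - y[_IDX["activity"]]) / cfg.surrogate.tau_act
        return dy

    def _solve_segment(self, y0, t_span, t_eval, inputs, lname, cmro_gain):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # LSODA chatter on tiny steps
            sol = solve_ivp(
                self.rhs, t_span, y0, t_eval=t_eval,
                method=self.config.solver.method,
                rtol=self.config.solver.rtol, atol=self.config.solver.atol,
                args=(inputs, lname, cmro_gain))
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationFailureError(
                f"ODE solver failed on segment {t_span}: {sol.message}",
                state_dump=self.unpack(y0))
        return sol


def equilibrate(model: CoupledModel, lname: bool = False,
                baseline_duration: float = 60000.0,
                tol: float = 1e-9) -> np.ndarray:
    """Integrate with all inputs off until the resting fixed point is reached.

    Starts from the analytic baseline and integrates in chunks until the
    max absolute state derivative falls below ``tol`` per ms or
    ``baseline_duration`` is exhausted (then a warning is emitted).
    """
    y = model.baseline_guess(lname=lname)
    inputs = (0.0, 0.0, 0.0, 0.0)
    chunk = 5000.0
    elapsed = 0.0
    while True:
        if np.max(np.abs(model.rhs(0.0, y, inputs, lname, 0.0))) < tol:
            return y
        if elapsed >= baseline_duration:
            warnings.warn(
                "equilibration did not reach derivative tolerance "
                f"{tol} within {baseline_duration} ms", RuntimeWarning)
            return y
        sol = model._solve_segment(y, (0.0, chunk), None, inputs, lname, 0.0)
        y = sol.y[:, -1]
        elapsed += chunk


def run_condition(protocol: StimulusProtocol,
                  config: Config | None = None) -> hemo.HemoTrace:
    """Simulate one experimental condition and return its hemoglobin trace.

    Equilibrates at rest (with the L-NAME switch already applied, matching
    drug injection before stimulation), integrates the coupled system over
    ``[0, t0 + duration + post_window]`` piecewise across the stimulus
    breakpoints, and converts radius/balloon states to fractional HbO, HbR
    and HbT changes. Deterministic: there are no stochastic terms.
    """
    model = CoupledModel(config)
    cfg = model.config
    bal = cfg.balloon
    cmro_gain = bal.cmro_gain if protocol.kind == "whisker" else bal.cmro_gain_opto

    y0 = equilibrate(model, lname=protocol.lname,
                     baseline_duration=protocol.baseline_duration)

    t_end = protocol.t0 + protocol.duration + cfg.solver.post_window
    t_out = np.arange(0.0, t_end + 0.5 * cfg.solver.dt_out, cfg.solver.dt_out)

    # smooth segments between input discontinuities
    breaks = sorted({0.0, protocol.t0,
                     protocol.t0 + protocol.duration * protocol.npy_width_factor,
                     protocol.t0 + protocol.duration, t_end})
    breaks = [b for b in breaks if 0.0 <= b <= t_end]

    ys = np.empty((N_STATES, t_out.size))
    y = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        inputs = route_inputs(protocol, 0.5 * (a + b))
        if b < t_end:
            pos = np.nonzero((t_out >= a) & (t_out < b))[0]
        else:
            pos = np.nonzero((t_out >= a) & (t_out <= b))[0]
        te = t_out[pos]
        # always land exactly on the segment end to chain the state
        t_eval = te if te.size and te[-1] == b else np.concatenate([te, [b]])
        sol = model._solve_segment(y, (a, b), t_eval, inputs,
                                   protocol.lname, cmro_gain)
        ys[:, pos] = sol.y[:, :pos.size]
        y = sol.y[:, -1]

    radius = ys[_IDX["radius"]]
    q = ys[_IDX["dhb"]]
    volume = ys[_IDX["volume"]]
    activity = ys[_IDX["activity"]]
    cbf = hemo.cbf_from_radius(radius)
    cmro = np.array([hemo.cmro_from_activity(max(a, 0.0), cmro_gain)
                     for a in activity])
    d_hbr, d_hbt, d_hbo = hemo.hb_outputs(
        q, cbf, cmro, closure=bal.hbt_closure, volume=volume)
    return hemo.HemoTrace(t=t_out, d_hbo=d_hbo, d_hbr=d_hbr, d_hbt=d_hbt)
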