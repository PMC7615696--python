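"""Interneuron signalling kinetics: GABA, NPY, glutamate and neuronal NO.

The inhibitory-interneuron compartment is described by four scalar ODEs.
GABA and NPY are nondimensionalised so that a sustained stimulation drives
them to order-one elevations above a resting baseline; glutamate is produced
either by K+-triggered vesicle release from the excitatory neuron or by
GABA-T-catalysed degradation of GABA. The GABA transaminase (GABA-T)
activity is the model's NO-sensitive element: it is a decreasing sigmoid of
neuronal NO, so that abundant NO protects GABA from degradation while NO
blockade (L-NAME) doubles the degradation rate and halves the stimulated
GABA elevation.

Neuronal NO itself is represented by a first-order production/decay
surrogate with a stimulation-gated source; the L-NAME condition zeroes both
the source and the resting supply so NO relaxes to zero with no other
parameter changed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidProtocolError
from .params import SignallingParams

__all__ = [
    "SignallingState",
    "heaviside_input",
    "gaba_t_activity",
    "gaba_degradation_rate",
    "gaba_rhs",
    "npy_rhs",
    "glutamate_release",
    "glu_rhs",
    "no_rhs",
]


@dataclass
class SignallingState:
    """Instantaneous interneuron signalling state.

    Attributes
    ----------
    gaba, npy, glu:
        Nondimensional concentrations (1 = order of the stimulated level).
    no_n:
        Neuronal nitric-oxide concentration in uM.
    """

    gaba: float
    npy: float
    glu: float
    no_n: float


def heaviside_input(t: float, t0: float, dt: float) -> float:
    """Rectangular stimulation input: 1 strictly inside (t0, t0 + dt), else 0.

    Both boundaries are exclusive; the input is 0 exactly at onset and offset.

    Raises
    ------
    InvalidProtocolError
        If ``dt`` is not positive.
    """
    if dt <= 0:
        raise InvalidProtocolError(f"stimulus duration must be > 0, got {dt}")
    return 1.0 if t0 < t < t0 + dt else 0.0


def gaba_t_activity(no_n: float, p: SignallingParams) -> float:
    """GABA-T activity as a decreasing sigmoid of neuronal NO.

    Returns ``((gt_max + gt_min) - (gt_max - gt_min) * tanh((no_n -
    gt_midpoint) / gt_slope)) / 2``, which lies strictly inside
    ``(gt_min, gt_max)`` and is monotone non-increasing in NO. At the
    midpoint the activity is the mean of the two bounds; with NO absent it
    saturates near ``gt_max`` (enzyme uninhibited) and with NO abundant near
    ``gt_min``.
    """
    z = (no_n - p.gt_midpoint) / p.gt_slope
    return 0.5 * ((p.gt_max + p.gt_min) - (p.gt_max - p.gt_min) * np.tanh(z))


def gaba_degradation_rate(gt_act: float, p: SignallingParams) -> float:
    """Effective GABA degradation rate: the base rate scaled by GABA-T activity."""
    return p.beta_gaba * gt_act


def gaba_rhs(state: SignallingState, i_h: float, p: SignallingParams,
             gt_act: float | None = None) -> float:
    """Time derivative of nondimensional GABA (per ms).

    Linear production/degradation kinetics:
    ``-kappa_gaba * (gaba - gaba_base) + alpha_gaba * i_h`` with
    ``kappa_gaba = beta_gaba * gt_act``. The resting baseline is a fixed
    point when the input is off; under a sustained input the elevation
    approaches ``alpha_gaba / kappa_gaba``, hence it is inversely
    proportional to GABA-T activity.
    """
    if gt_act is None:
        gt_act = gaba_t_activity(state.no_n, p)
    kappa = gaba_degradation_rate(gt_act, p)
    return -kappa * (state.gaba - p.gaba_base) + p.alpha_gaba * i_h


def npy_rhs(state: SignallingState, i_h_npy: float, p: SignallingParams) -> float:
    """Time derivative of nondimensional NPY (per ms).

    Same linear structure as GABA but with a fixed degradation rate. The
    driving indicator uses the NPY-specific pulse, which is half the width
    of the GABA pulse under the default protocol.
    """
    return -p.beta_npy * (state.npy - p.npy_base) + p.alpha_npy * i_h_npy


def glutamate_release(ke: float, p: SignallingParams) -> float:
    """K+-triggered glutamate release from the excitatory neuron.

    A saturating sigmoid of extracellular K+: half-maximal at ``ke_switch``,
    approaching ``glu_max`` for strongly elevated K+ and essentially zero at
    resting K+.
    """
    return 0.5 * p.glu_max * (1.0 + np.tanh((ke - p.ke_switch) / p.glu_slope))


def glu_rhs(state: SignallingState, ke: float, p: SignallingParams,
            gt_act: float | None = None) -> float:
    """Time derivative of nondimensional glutamate (per ms).

    Sources are the K+-triggered release and the GABA degradation product
    ``kappa_gaba * gaba``; the sink is first-order decay. With both sources
    off, glutamate relaxes to zero.
    """
    if gt_act is None:
        gt_act = gaba_t_activity(state.no_n, p)
    kappa = gaba_degradation_rate(gt_act, p)
    return glutamate_release(ke, p) + kappa * state.gaba - p.beta_glu * state.glu


def no_rhs(state: SignallingState, i_h: float, lname: bool,
           p: SignallingParams) -> float:
    """Time derivative of neuronal NO (uM per ms).

    First-order kinetics with a stimulation-gated source. With the NOS
    blocker active (``lname``) both the source and the resting supply are
    zeroed, so NO decays to zero; otherwise NO rests at ``no_rest`` and is
    elevated during stimulation.
    """
    gate = 0.0 if lname else 1.0
    return (-p.no_beta * (state.no_n - p.no_rest * gate)
            + p.no_alpha * i_h * gate)
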