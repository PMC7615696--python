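# nvcgaba

A desk-scale simulator of neurovascular coupling driven by GABAergic
interneurons, for researchers studying how inhibitory signalling shapes the
cortical hemodynamic response. It models the nitric-oxide-mediated balance
between two opposing interneuron pathways — GABA (dilation, via Cl⁻
channels on the vascular smooth muscle) and neuropeptide Y (constriction,
via the voltage-operated Ca²⁺ channel) — and produces fractional
oxy-/deoxy-/total-hemoglobin (HbO/HbR/HbT) time series for four
experimental conditions: whisker (somatosensory) or optogenetic (nNOS
interneuron) stimulation, each with or without the NOS blocker L-NAME.

## Model

The interneuron compartment holds four ODE states. Nondimensional GABA and
NPY follow linear production/degradation kinetics driven by a rectangular
stimulus input `I_H(t)`:

    dGABA/dt = −κ_GABA (GABA − GABA_base) + α_GABA I_H(t),   κ_GABA = β_GABA · GT_act
    dNPY/dt  = −β_NPY (NPY − NPY_base) + α_NPY I_H,npy(t)
    dGlu/dt  = f(K_e) + κ_GABA GABA − β_Glu Glu

where the NPY pulse is half the width of the GABA pulse, and `f(K_e)` is a
sigmoidal glutamate release triggered when extracellular K⁺ exceeds 5 mM.
The GABA transaminase activity `GT_act` is a decreasing sigmoid of neuronal
NO, bounded between 1 (NO abundant) and 2 (NO absent):

    GT_act = ½[(GT_max + GT_min) − (GT_max − GT_min) tanh((NO_n − GT_mid)/GT_slope)]

so NOS blockade doubles GABA degradation and halves the stimulated GABA
elevation — the quantitative core of the GABA–NPY balance. NO itself is a
first-order production/decay state; L-NAME is a pure switch zeroing its
production, with no other parameter changed between conditions.

Two channel fluxes couple signalling to the vessel: a GABA-gated Cl⁻ flux
`g_GABA(GABA)·(v − E_GABA)` with `E_GABA = −75 mV` (hyperpolarising, hence
dilating), and an NPY-modulated VOCC Ca²⁺ flux whose conductance rises from
`G_Ca,i` at NPY = 0 to `1.05·G_Ca,i` at NPY = 1 (constricting). These are
embedded in a six-state first-order electro-vascular surrogate
(K_e, K_p, v_k, v_i, Ca_i, radius) preserving the mechanistic sign chains;
the radius drives cerebral blood flow (∝ radius⁴) into a Buxton-type venous
balloon whose states give `ΔHbR = q − 1`, `ΔHbT = CBF·q/CMRO − 1` and
`ΔHbO = ΔHbT − ΔHbR` (hemoglobin conservation, exact). See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import numpy as np
from nvcgaba import StimulusProtocol, run_condition

for kind, lname in [("whisker", False), ("optogenetic", False), ("optogenetic", True)]:
    tr = run_condition(StimulusProtocol(kind=kind, lname=lname))
    i = np.argmax(np.abs(tr.d_hbt))
    print(f"{kind:12s} lname={lname}: peak dHbT {tr.d_hbt[i]:+.3f} at t={tr.t[i]/1000:.2f}s")
```

prints

```
whisker      lname=False: peak dHbT +0.470 at t=4.68s
optogenetic  lname=False: peak dHbT +0.454 at t=4.28s
optogenetic  lname=True: peak dHbT +0.105 at t=4.29s
```

Whisker stimulation (2 s starting at t = 2 s) gives classic functional
hyperemia: HbT and HbO rise while HbR falls, essentially unchanged by
L-NAME. Optogenetic stimulation without the drug shows an early HbR rise
with an HbO/HbT dip (the fast NPY constriction) before the slower GABA
dilation takes over; with L-NAME the doubled GABA degradation weakens the
dilating pathway and the response collapses toward the NPY-dominated,
constriction-shifted shape — the peak dilation drops more than four-fold.

The same runs are available from the shell:

```bash
nvcgaba run --condition optogenetic --lname --out trace.csv
nvcgaba make-reference --condition optogenetic --lname --seed 1 --out ref.csv
nvcgaba compare --trace trace.csv --reference ref.csv --out metrics.json
nvcgaba sweep --condition whisker --param beta_gaba --values 1.1e-3,2.2e-3 --out-dir sweep/
```

`make-reference` emits *synthetic* reference traces with the qualitative
per-condition morphology (the experimental 2D-OIS data are not published as
numeric series); `compare` reports per-channel RMSE, peak errors and the
fraction of samples inside the reference ± s.d. band.

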