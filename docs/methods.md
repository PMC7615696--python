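# Methods

## Scope and model structure

`nvcgaba` simulates the hemodynamic consequences of activating GABAergic
(NPY/nNOS-expressing) interneurons versus somatosensory (whisker-driven)
neurons in mouse cortex. The full coupled system has 13 ODE states in three
blocks:

1. **Interneuron signalling** (GABA, NPY, Glu, NO): the model's scientific
   core. GABA and NPY are nondimensional (1 ≈ the stimulated level) with
   linear production/degradation kinetics; glutamate is sourced by
   K⁺-triggered release and by GABA-T-catalysed GABA degradation; GABA-T
   activity is a decreasing tanh sigmoid of neuronal NO bounded in
   [GT_min, GT_max] = [1, 2].
2. **Electro-vascular surrogate** (K_e, K_p, v_k, v_i, Ca_i, radius): a
   reduced-order replacement for a full multicellular neurovascular-unit
   electrophysiology. Every state has first-order kinetics toward an
   algebraic target; the channel fluxes that carry the science — the
   GABA-gated Cl⁻ flux and the NPY-modulated VOCC flux — keep their full
   biophysical forms.
3. **Balloon hemodynamics** (venous volume v, deoxyhemoglobin q, plus a
   metabolic activity lag): the standard Buxton venous balloon with Grubb
   outflow and flow-dependent oxygen extraction.

Time is in milliseconds throughout: the tabulated conductances are per ms
and the kinetic rates (≈ 2.2×10⁻³ ms⁻¹) give ~455 ms time constants,
consistent with 2-s stimulations.

## Why a surrogate, and what it assumes

The mechanisms to be reproduced are sign chains, not membrane-level
waveforms: neuronal K⁺ release → astrocytic relay to the perivascular
space → KIR-like SMC hyperpolarisation → VOCC closure → dilation; NPY →
VOCC conductance increase → Ca²⁺ influx → constriction; GABA → Cl⁻ flux
toward E_GABA = −75 mV → hyperpolarisation → dilation. The surrogate
implements each arrow as a saturating first-order element:

* `dK_e/dt = (K_e,base − K_e)/τ_ke + k_amp·I_ke` with K_e,base = 3 mM,
  k_amp·τ_ke = 5 mM, spanning the physiological 3–10 mM range and crossing
  the 5 mM glutamate-release switch during whisker stimulation.
* K_p follows K_e with a first-order lag (the astrocytic relay).
* `v_i` relaxes (τ = 200 ms) to `v_rest − kir_amp·tanh((K_p − 3)/kir_scale)`
  while the GABA Cl⁻ flux pulls it toward E_GABA with voltage gain
  `w_gaba = 4000 mV·µM⁻¹` (an inverse-capacitance-like conversion chosen so
  a fully open GABA channel hyperpolarises the SMC by roughly 10 mV at
  steady state).
* SMC Ca²⁺ relaxes to the VOCC flux normalised by its resting value, so the
  baseline is exactly Ca_i = 1; the radius relaxes to
  `1 + 0.15·tanh((1 − Ca_i)/0.5)`, a monotone saturating vasoreactivity
  curve with at most ±15% radius excursion.

The resting potentials (−45 mV SMC, −80 mV astrocyte) and VOCC constants
(reversal 100 mV, half-activation −24 mV, slope 8.5 mV) are standard
neurovascular-literature values. A 20-HETE-like depolarising term driven by
glutamate exists as an optional gain, default zero: with it forced off the
hemodynamic profiles are not meaningfully different, so the arachidonic
acid cascade is deliberately out of scope.

The analytic resting fixed point of the surrogate is computed in closed
form (the voltage equations are linear at rest) and verified by
equilibration; `equilibrate` integrates with all inputs off until the
maximum state derivative falls below 10⁻⁹ ms⁻¹.

## Conductance conventions

* The maximal GABA Cl⁻ conductance is 0.3 × the SMC Cl⁻ leak conductance:
  4.02×10⁻⁷ = 0.3 × 1.34×10⁻⁶ µM·mV⁻¹·ms⁻¹. The GABA sigmoid uses midpoint
  0.5 and width 0.15 (where the descriptive text and the parameter table
  disagree — e.g. a 0.8 midpoint in the text — the table value is the
  default and both are noted in the registry).
* The NPY-dependent VOCC conductance must satisfy two stated endpoints:
  `g_VOCC(0) = G_Ca,i` exactly and `g_VOCC(1) = 1.05·G_Ca,i` exactly. The
  raw half-amplitude tanh form misses both (at NPY = 0 it already sits
  ~2.5% below base), so the default `endpoint` convention affinely rescales
  the sigmoid `σ(x) = ½(1 + tanh((x − 0.5)/0.15))` to
  `S(x) = (σ(x) − σ(0))/(σ(1) − σ(0))` and uses
  `g_VOCC = G_Ca,i(1 + 0.05·S)`. The literal form is available via
  `vocc_sigmoid: literal` for sensitivity checks.
* The fractional VOCC increase is 0.05 (the tabulated entry is a
  placeholder; the descriptive value is used).

## Signalling conventions

* GABA_base = NPY_base = 0 by default, consistent with the
  nondimensionalisation in which the resting concentration is zero; the
  baseline-shifted and baseline-free forms of the GABA equation then
  coincide. Both baselines are config-exposed.
* Glu_max = 1 (nondimensional; not tabulated).
* The stimulus input is a strict-inequality rectangular window: 1 for
  t₀ < t < t₀ + Δt, 0 at and outside the boundaries. Carrier frequencies
  (5 Hz whisker, 99 Hz photostimulation) are not resolved; the envelope is
  the input.
* **NO kinetics.** No NO ODE is printed in the source model, so a
  first-order surrogate is used: decay rate 2.2×10⁻³ ms⁻¹ (matching the
  other kinetic scales) toward a resting level NO_rest = 0.02047 µM, with a
  stimulation-gated source sized so the sustained elevation is ~10×NO_rest
  (deep in the GABA-T-protective saturation). L-NAME (reported >90% NOS
  inhibition) is modelled as a 100% switch: both the source and the resting
  supply are zeroed and NO decays to 0. Only the resting level and the
  switch behaviour are externally constrained; the two rate constants are
  config-exposed surrogate choices.
* **Known tension, implemented as printed:** with midpoint 0.06 µM and
  width 0.02128 µM the activity sigmoid evaluates to ≈1.976 at NO_rest,
  although GT_min = 1 is described as the activity *at rest*. The
  50%/100% blockade claims are therefore stated — and verified — against
  the sigmoid's saturation limits (GT_min, GT_max), not its value at
  NO_rest.

## Stimulus routing and conditions

Whisker stimulation drives extracellular K⁺ and NO; optogenetic
stimulation drives GABA, NPY and NO (the targeted interneurons co-release
all three). The NPY pulse width is half the GABA pulse width
(`npy_width_factor = 0.5`) — this is what produces the early HbR rise and
HbO/HbT dip before the GABA dilation takes over. Both stimuli default to
2 s duration, onset at t = 2 s, with an 18 s post-stimulus window sampled
every 10 ms; the integration is piecewise across the input discontinuities
with LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ (the system is only mildly stiff).
Whether whisker stimulation should also recruit a small GABA/NPY component
is left unrouted by default. The model is deterministic, so one run per
condition suffices (trial averaging is a property of the data, not the
model).

## Hemodynamic closure

Balloon constants are standard literature values (τ = 2000 ms, Grubb
exponent 0.38, resting extraction fraction E₀ = 0.4), config-exposed.
CMRO₂ is `1 + gain·a(t)` with `a` the stimulus indicator smoothed by a 1 s
lag; the gain defaults to 0.1 for whisker (a modest metabolic load from
excitatory activity) and 0 for optogenetic stimulation (inhibitory
activation), both overridable. Total hemoglobin uses the multiplicative
closure `ΔHbT = CBF·q/CMRO − 1` normalised to zero at baseline; the
conventional volume closure `ΔHbT = v − 1` is available via
`hbt_closure: volume`. HbO is defined by conservation and HbT is re-summed
as `ΔHbO + ΔHbR` so the conservation identity holds bit-exactly at every
output sample.

## Synthetic references and what passing means

`make_reference` produces gamma-difference templates with the documented
per-condition morphology plus seeded Gaussian noise averaged over 12
pseudo-trials (onset lag 300 ms, peaks at 1.5–2.5 s — generic
hemodynamic-response timing). These are synthetic stand-ins: the
experimental optical-imaging traces are not available as numbers. Tests
against them demonstrate that the comparison tooling and the qualitative
shape logic are correct; they say nothing about quantitative agreement
with real mouse data. Likewise, the simulated fractional changes are
larger than typical experimental amplitudes (the radius⁴ flow closure is
steep); the package's claims are the analytic parameter relationships and
the per-condition sign structure, both of which the test suite checks
directly.

## Numerical and degenerate-input choices

* Strict input-window inequalities mean a sample exactly at onset/offset
  sees input 0; integration segments are split at the breakpoints so the
  solver never steps across a discontinuity.
* NO is clamped at 0 inside the coupled right-hand side before the
  activity sigmoid is evaluated (it can numerically undershoot by less
  than solver tolerance under the L-NAME switch).
* Non-positive balloon volume, solver failure or non-finite state raise an
  integration-failure error carrying a state dump.
* The equilibration warns (rather than fails) if the derivative tolerance
  is not met within the configured baseline duration.

## Known limitations

* Post-stimulus oscillations seen experimentally are outside the model
  class (no delayed feedback loop is included).
* The surrogate reproduces sign chains and timescales, not membrane-level
  traces; its constants are order-of-magnitude physiological choices, not
  fits.
* Absolute (µM) hemoglobin quantification, the spectroscopic forward
  model, and anaesthesia or inter-animal variability are out of scope.
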